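"""Attributable-mortality estimation for long-term PM2.5 exposure.

Premature deaths for four endpoints — chronic obstructive pulmonary disease
(COPD), ischemic heart disease (IHD), stroke, and lung cancer (LC) — are
computed from gridded age-structured population, baseline mortality rates,
and a hazard-curve relative risk RR(c).  The default hazard family is the
GEMM form

    RR(c) = exp( theta * log(1 + z/alpha) / (1 + exp(-(z - mu)/nu)) ),
    z = max(0, c - c0),

with a log-linear alternative exp(beta * z) selectable per endpoint.  Deaths
attributable to exposure c are Pop * BMR * (1 - 1/RR(c)) summed over cells
and strata; avoided deaths of a control scenario are the baseline-minus-
scenario difference, monetized at the value of statistical life (VSL).

The shipped hazard parameters and the VSL are editable placeholder tables of
GEMM-like magnitude, not authoritative epidemiology.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .synthetic_world import GridSpec

ENDPOINTS = ("COPD", "IHD", "stroke", "LC")
#: 5-year age bands from 25 to 85+.
AGE_BANDS = tuple(f"{a}-{a + 4}" for a in range(25, 85, 5)) + ("85+",)


class HealthError(ValueError):
    pass


@dataclass
class RRParams:
    """Hazard-curve parameters for one endpoint."""

    theta: float
    alpha: float
    mu: float
    nu: float
    c0: float = 2.4          # counterfactual concentration (µg/m³)
    form: str = "gemm"       # or "loglinear" (theta acts as beta)

    def validate(self) -> None:
        if self.alpha <= 0 or self.nu <= 0 or self.c0 < 0:
            raise HealthError("invalid hazard parameters")
        if self.form not in ("gemm", "loglinear"):
            raise HealthError(f"unknown hazard form {self.form!r}")


#: Placeholder hazard parameters of GEMM-like magnitude per endpoint.
DEFAULT_RR_PARAMS: Dict[str, RRParams] = {
    "COPD": RRParams(theta=0.2510, alpha=6.5, mu=2.5, nu=32.0),
    "IHD": RRParams(theta=0.2969, alpha=1.9, mu=12.0, nu=40.2),
    "stroke": RRParams(theta=0.2720, alpha=6.2, mu=16.7, nu=23.7),
    "LC": RRParams(theta=0.2942, alpha=6.2, mu=9.3, nu=29.8),
}


@dataclass
class ValuationParams:
    vsl_usd: float = 1.0e6   # placeholder VSL, nominal USD per death
    reference_year: int = 2020

    def validate(self) -> None:
        if self.vsl_usd <= 0:
            raise HealthError("VSL must be positive")


def relative_risk(c, endpoint: str, params: Optional[Dict[str, RRParams]] = None):
    """RR(c) for one endpoint; c may be scalar or array, in µg/m³.

    RR equals 1 at and below the counterfactual c0 and is non-decreasing.
    """
    params = params or DEFAULT_RR_PARAMS
    if endpoint not in params:
        raise HealthError(f"unknown endpoint {endpoint!r}")
    p = params[endpoint]
    p.validate()
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise HealthError("negative concentrations")
    z = np.maximum(0.0, c - p.c0)
    if p.form == "loglinear":
        return np.exp(p.theta * z)
    logistic = 1.0 / (1.0 + np.exp(-(z - p.mu) / p.nu))
    return np.exp(p.theta * np.log1p(z / p.alpha) * logistic)


def synthetic_population(grid: GridSpec, total: float = 4.0e8,
                         decay_nm: float = 150.0) -> pd.DataFrame:
    """Coastal-weighted synthetic population by age band.

    Density on land falls off exponentially with distance from the coast;
    sea cells hold zero.  Returns a DataFrame with one column per age band;
    each column is a flattened (ny*nx) population-count field.  The age
    structure is an aging-society profile, constant across space.
    """
    w = np.where(grid.land_mask, np.exp(grid.dist_coast_nm / decay_nm), 0.0)
    w = w / w.sum() * total
    # fractions over 25..85+, mildly decreasing with a retirement bulge
    base = np.array([1.3, 1.3, 1.25, 1.2, 1.15, 1.1, 1.0, 0.85, 0.65,
                     0.45, 0.28, 0.15, 0.08])
    frac = base / base.sum()
    return pd.DataFrame({band: w.ravel() * f for band, f in zip(AGE_BANDS, frac)})


def synthetic_mortality_table() -> pd.DataFrame:
    """Baseline mortality rates (deaths/person/year), endpoint x age band.

    Rates rise roughly exponentially with age, scaled so all-cause totals
    for the four endpoints sit at plausible magnitudes.
    """
    ages = np.arange(len(AGE_BANDS))
    scale = {"COPD": 6e-6, "IHD": 1.2e-5, "stroke": 1.4e-5, "LC": 8e-6}
    growth = {"COPD": 1.62, "IHD": 1.55, "stroke": 1.55, "LC": 1.45}
    data = {ep: np.minimum(scale[ep] * growth[ep] ** ages, 0.2)
            for ep in ENDPOINTS}
    return pd.DataFrame(data, index=list(AGE_BANDS)).T


def attributable_deaths(conc: np.ndarray, population: pd.DataFrame,
                        bmr: pd.DataFrame,
                        rr_params: Optional[Dict[str, RRParams]] = None
                        ) -> pd.DataFrame:
    """Premature deaths attributable to exposure, endpoint x age band.

    deaths[e, a] = sum_cells Pop[a] * BMR[e, a] * (1 - 1/RR_e(c)).
    """
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise HealthError("negative concentrations")
    flat = conc.ravel()
    if len(population) != flat.size:
        raise HealthError("population grid does not match concentration field")
    out = {}
    for ep in ENDPOINTS:
        rr = relative_risk(flat, ep, rr_params)
        af = 1.0 - 1.0 / rr
        out[ep] = {band: float((population[band].to_numpy() *
                                bmr.loc[ep, band] * af).sum())
                   for band in AGE_BANDS}
    df = pd.DataFrame(out).T
    df.index.name = "endpoint"
    return df


@dataclass
class BurdenResult:
    """Avoided deaths of a scenario vs baseline, and their monetary value."""

    scenario_id: str
    avoided_by_stratum: pd.DataFrame       # endpoint x age band
    avoided_by_endpoint: pd.Series
    avoided_total: float
    value_usd: float
    vsl_usd: float


def avoided_deaths_and_value(baseline_conc: np.ndarray, scenario_conc: np.ndarray,
                             population: pd.DataFrame, bmr: pd.DataFrame,
                             rr_params: Optional[Dict[str, RRParams]] = None,
                             valuation: Optional[ValuationParams] = None,
                             scenario_id: str = "") -> BurdenResult:
    """Scenario-vs-baseline avoided premature deaths, monetized at the VSL."""
    if np.shape(baseline_conc) != np.shape(scenario_conc):
        raise HealthError("concentration grids do not match")
    valuation = valuation or ValuationParams()
    valuation.validate()
    d_base = attributable_deaths(baseline_conc, population, bmr, rr_params)
    d_scen = attributable_deaths(scenario_conc, population, bmr, rr_params)
    avoided = d_base - d_scen
    by_endpoint = avoided.sum(axis=1)
    total = float(by_endpoint.sum())
    return BurdenResult(
        scenario_id=scenario_id,
        avoided_by_stratum=avoided,
        avoided_by_endpoint=by_endpoint,
        avoided_total=total,
        value_usd=total * valuation.vsl_usd,
        vsl_usd=valuation.vsl_usd,
    )
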