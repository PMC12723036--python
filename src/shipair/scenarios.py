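"""Emission-reduction scenario construction, application, and benefit fields.

Idealized set (210 scenarios): ten shipping-SO2 reduction levels, a full
10 x 10 grid of joint shipping NOx/VOC reductions, and a full 10 x 10 grid of
joint land NOx/VOC reductions.  Policy set (5 scenarios): two sulfur-control
areas (ultra-low-sulfur fuel inside 12 Nm / 200 Nm) and three NOx-control
areas (Tier III inside ports / 12 Nm / 200 Nm for the post-2016 fleet).

A scenario is a per-(source-group, species) multiplicative factor applied
inside a spatial zone mask; benefits are baseline-minus-scenario differences
of four-month-mean shipping-related PM2.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np

from .synthetic_world import (COASTAL_REGIONS, GridSpec, EmissionBundle,
                              MonthSample, LAND_SPECIES, MONTHS, SHIP_SPECIES,
                              surrogate_chemistry)

ZONE_NAMES = ("ports", "nm12", "nm200", "mainland")


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class ZoneMask:
    name: str
    mask: np.ndarray


@dataclass
class ScalingScenario:
    """Uniform in-zone scaling of selected (source-group, species) pairs.

    ``factors`` maps ("land" | "shipping", species) to a scale in [0, 1];
    unlisted pairs keep factor 1.  ``zone`` names the spatial mask the
    scaling applies within.
    """

    id: str
    factors: Dict[Tuple[str, str], float]
    zone: str
    description: str = ""

    def __post_init__(self):
        for (grp, sp), f in self.factors.items():
            if not (0.0 <= f <= 1.0):
                raise ScenarioError(f"factor for {(grp, sp)} outside [0, 1]: {f}")
            if grp not in ("land", "shipping"):
                raise ScenarioError(f"unknown source group {grp!r}")
        if self.zone not in ZONE_NAMES:
            raise ScenarioError(f"unknown zone {self.zone!r}")


def coastal_zones(grid: GridSpec) -> Dict[str, ZoneMask]:
    """Derive the nested control zones from the grid's signed coast distance.

    nm12 and nm200 are sea cells within 12 and 200 Nm of the coastline;
    ports are the grid's designated high-traffic sea cells; mainland is all
    land cells of the (single-country) domain.  Raises if any zone is empty.
    """
    sea = ~grid.land_mask
    d = grid.dist_coast_nm
    zones = {
        "ports": ZoneMask("ports", grid.port_mask.copy()),
        "nm12": ZoneMask("nm12", sea & (d <= 12.0) | grid.port_mask),
        "nm200": ZoneMask("nm200", sea & (d <= 200.0) | grid.port_mask),
        "mainland": ZoneMask("mainland", grid.land_mask.copy()),
    }
    for name, z in zones.items():
        if not z.mask.any():
            raise ScenarioError(f"zone {name!r} is empty; grid too small")
    if not (zones["ports"].mask <= zones["nm12"].mask).all() or \
            not (zones["nm12"].mask <= zones["nm200"].mask).all():
        raise ScenarioError("zone nesting violated (ports ⊆ nm12 ⊆ nm200)")
    return zones


def build_idealized_set() -> list:
    """The 210 idealized scenarios.

    S1..S10: shipping SO2 cut 10%..100% inside nm200.
    N{i}V{j}, i,j in 1..10: shipping NOx cut 10i% and VOC cut 10j% inside nm200.
    LN{i}V{j}: the same joint cuts for land NOx/VOC across the mainland.
    """
    out = []
    for i in range(1, 11):
        out.append(ScalingScenario(
            id=f"S{i}", zone="nm200",
            factors={("shipping", "SO2"): 1.0 - 0.1 * i},
            description=f"shipping SO2 -{10 * i}% within 200 Nm"))
    for i in range(1, 11):
        for j in range(1, 11):
            out.append(ScalingScenario(
                id=f"N{i}V{j}", zone="nm200",
                factors={("shipping", "NOx"): 1.0 - 0.1 * i,
                         ("shipping", "VOC"): 1.0 - 0.1 * j},
                description=f"shipping NOx -{10 * i}%, VOC -{10 * j}% within 200 Nm"))
    for i in range(1, 11):
        for j in range(1, 11):
            out.append(ScalingScenario(
                id=f"LN{i}V{j}", zone="mainland",
                factors={("land", "NOx"): 1.0 - 0.1 * i,
                         ("land", "VOC"): 1.0 - 0.1 * j},
                description=f"land NOx -{10 * i}%, VOC -{10 * j}% on the mainland"))
    return out


def build_policy_set(fleet_post2016_fraction: float = 0.5,
                     sulfur_baseline: float = 0.5,
                     sulfur_limit: float = 0.1,
                     tier3_cut: float = 0.8,
                     seca_pm_cofactor: float = 0.85) -> list:
    """The five prospective control-area policy scenarios.

    SECA-12/SECA-200: ultra-low-sulfur fuel (``sulfur_limit`` % m/m against
    the ``sulfur_baseline`` % fleet fuel) inside 12 / 200 Nm; shipping SO2
    scales by limit/baseline and primary PM by ``seca_pm_cofactor``.
    NECA-ports/-12/-200: Tier III (``tier3_cut`` NOx reduction per compliant
    ship) for the post-2016 fleet fraction inside the respective zone.
    """
    if not (0.0 <= fleet_post2016_fraction <= 1.0):
        raise ScenarioError("fleet fraction must lie in [0, 1]")
    if sulfur_limit > sulfur_baseline:
        raise ScenarioError("sulfur limit above baseline sulfur content")
    so2_factor = sulfur_limit / sulfur_baseline
    nox_factor = 1.0 - tier3_cut * fleet_post2016_fraction
    seca = {("shipping", "SO2"): so2_factor, ("shipping", "PM"): seca_pm_cofactor}
    neca = {("shipping", "NOx"): nox_factor}
    return [
        ScalingScenario("SECA-12", dict(seca), "nm12",
                        "0.1% sulfur fuel within 12 Nm"),
        ScalingScenario("SECA-200", dict(seca), "nm200",
                        "0.1% sulfur fuel within 200 Nm"),
        ScalingScenario("NECA-ports", dict(neca), "ports",
                        "Tier III for post-2016 ships in port areas"),
        ScalingScenario("NECA-12", dict(neca), "nm12",
                        "Tier III for post-2016 ships within 12 Nm"),
        ScalingScenario("NECA-200", dict(neca), "nm200",
                        "Tier III for post-2016 ships within 200 Nm"),
    ]


def apply_scenario(emissions: EmissionBundle, scenario: ScalingScenario,
                   zones: Dict[str, ZoneMask]) -> EmissionBundle:
    """Scale the targeted species inside the scenario zone; input untouched."""
    out = emissions.copy()
    mask = zones[scenario.zone].mask
    for (grp, sp), f in scenario.factors.items():
        if grp == "land":
            j = LAND_SPECIES.index(sp)
            out.land[:, j, mask] *= f
        else:
            j = SHIP_SPECIES.index(sp)
            out.shipping[:, j, mask] *= f
    return out


IDENTITY_SCENARIO = ScalingScenario("BASE", {}, "nm200", "baseline, no scaling")


@dataclass
class BenefitResult:
    """Four-month-mean shipping-PM2.5 benefit of one scenario vs baseline."""

    scenario_id: str
    field: np.ndarray                      # µg/m³, baseline - scenario
    regional_means: Dict[str, float]       # all-coastal + CBS/SEC/SC
    scenario_mean_fields: Optional[dict] = None


def _regional_means(field: np.ndarray, grid: GridSpec) -> Dict[str, float]:
    means = {}
    coastal = grid.coastal_land_mask()
    means["all-coastal"] = float(field[coastal].mean()) if coastal.any() else np.nan
    for region in COASTAL_REGIONS:
        m = grid.region_mask(region)
        means[region] = float(field[m].mean()) if m.any() else np.nan
    return means


def benefit(shipping_pm_fn: Callable[[MonthSample], np.ndarray],
            baseline_samples: Sequence[MonthSample],
            scenario: ScalingScenario, grid: GridSpec) -> BenefitResult:
    """Annual-mean (four-month) shipping-PM2.5 benefit of a scenario.

    ``shipping_pm_fn(sample)`` evaluates shipping-related PM2.5 for a month
    sample — either through the surrogate truth or through a trained
    emulator.  The baseline set must cover the four modelled months; the
    benefit field is mean(baseline) - mean(scenario), so it is identically
    zero for the identity scenario and antisymmetric under swapping the two.
    """
    months = sorted({s.month_label for s in baseline_samples})
    missing = [m for m in MONTHS if m not in months]
    if missing:
        raise ScenarioError(f"baseline set missing months {missing}")
    zones = coastal_zones(grid)
    base_fields, scen_fields = [], []
    for s in baseline_samples:
        base_fields.append(shipping_pm_fn(s))
        scaled = apply_scenario(s.emissions, scenario, zones)
        s_scen = MonthSample(year_index=s.year_index, month_label=s.month_label,
                             emissions=scaled, met=s.met, truth=s.truth,
                             is_test=s.is_test)
        scen_fields.append(shipping_pm_fn(s_scen))
    field = np.mean(base_fields, axis=0) - np.mean(scen_fields, axis=0)
    return BenefitResult(scenario_id=scenario.id, field=field,
                         regional_means=_regional_means(field, grid))


def truth_shipping_pm(params) -> Callable[[MonthSample], np.ndarray]:
    """Surrogate-truth evaluator for :func:`benefit`."""
    def fn(sample: MonthSample) -> np.ndarray:
        bundle = surrogate_chemistry(sample.emissions, sample.met, params)
        return bundle.shipping_pm25()
    return fn


def emulator_shipping_pm(models: dict) -> Callable[[MonthSample], np.ndarray]:
    """Emulator evaluator: ``models`` maps month label -> TrainedEmulator."""
    from .emulator import predict_shipping_pm

    def fn(sample: MonthSample) -> np.ndarray:
        model = models[sample.month_label]
        return predict_shipping_pm(model, sample).shipping["pm25"]
    return fn


def response_surface(shipping_pm_fn, baseline_samples, scenarios, grid,
                     region: str = "all-coastal"):
    """Evaluate many scenarios; returns {scenario id -> regional benefit}."""
    out = {}
    for sc in scenarios:
        out[sc.id] = benefit(shipping_pm_fn, baseline_samples, sc,
                             grid).regional_means[region]
    return out
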