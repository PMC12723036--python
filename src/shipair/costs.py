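"""Emission-control cost accounting and the cost-benefit assembly.

Fuel-switch costs use the fuel-consumption method: R = sum(P_actual *
SFOC_load * dt) converted grams -> tons, and Cost = R * premium, with the
ultra-low-sulfur premium defaulting to the midpoint of the published
70–200 USD/ton price-difference range (135 USD/ton).  NOx abatement uses an
exponential unit-cost curve c(r) = a * exp(b * r) through literature-style
anchor points, hard-calibrated so the Tier III operating point costs
c(0.8) = 47 USD/kW, multiplied by the compliant fleet power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

GRAMS_PER_TON = 1.0e6

#: Annual fuel consumption of ships inside each control zone (tons).
DEFAULT_FUEL_TONS = {"nm12": 9.5e6, "nm200": 16.9e6}

#: Post-2016 fleet installed power inside each control zone (kW); synthetic
#: defaults of the magnitude implied by published average control costs.
DEFAULT_FLEET_KW = {"ports": 1.2e7, "nm12": 1.6e7, "nm200": 2.1e7}

#: Literature-style (reduction ratio, USD/kW) anchors for NOx abatement.
DEFAULT_NOX_ANCHORS = ((0.2, 10.0), (0.4, 18.0), (0.6, 30.0), (0.8, 47.0))

TIER3_CALIBRATION = (0.8, 47.0)  # Tier III operating point


class CostError(ValueError):
    pass


@dataclass
class FuelRecord:
    """One engine-operation record for the fuel-consumption method."""

    p_actual_kw: float
    sfoc_g_per_kwh: float
    duration_h: float

    def validate(self) -> None:
        if min(self.p_actual_kw, self.sfoc_g_per_kwh, self.duration_h) <= 0:
            raise CostError("fuel record fields must be positive")

    def tons(self) -> float:
        self.validate()
        return self.p_actual_kw * self.sfoc_g_per_kwh * self.duration_h / GRAMS_PER_TON


def premium_from_range(low: float, high: float) -> float:
    """Midpoint fuel-price premium of a published price-difference range."""
    if low < 0 or high < 0:
        raise CostError("prices must be non-negative")
    if low > high:
        raise CostError("low price above high price")
    return 0.5 * (low + high)


DEFAULT_PREMIUM = premium_from_range(70.0, 200.0)  # 135 USD/ton


def fuel_consumption_tons(records: Sequence[FuelRecord]) -> float:
    """Total fuel consumption R = sum(P_actual * SFOC_load * dt), in tons."""
    if not records:
        raise CostError("no fuel records supplied")
    return sum(r.tons() for r in records)


def fuel_switch_cost(consumption=None, premium: float = DEFAULT_PREMIUM,
                     records: Optional[Sequence[FuelRecord]] = None) -> float:
    """Fuel-switch cost in USD: consumption (tons) times premium (USD/ton).

    Pass either ``consumption`` in tons or ``records`` (not both).
    """
    if (consumption is None) == (records is None):
        raise CostError("supply exactly one of consumption (tons) or records")
    if premium < 0:
        raise CostError("premium must be non-negative")
    tons = fuel_consumption_tons(records) if records is not None else float(consumption)
    if tons < 0:
        raise CostError("consumption must be non-negative")
    return tons * premium


@dataclass
class NoxCostCurve:
    """Exponential NOx-abatement unit-cost curve c(r) = a * exp(b * r).

    Fitted in log space to the anchor table, then rescaled so the Tier III
    calibration point is matched exactly.
    """

    a: float
    b: float
    calibration: tuple = TIER3_CALIBRATION

    @classmethod
    def from_anchors(cls, anchors: Sequence[tuple] = DEFAULT_NOX_ANCHORS,
                     calibration: tuple = TIER3_CALIBRATION) -> "NoxCostCurve":
        r = np.array([a[0] for a in anchors], dtype=float)
        c = np.array([a[1] for a in anchors], dtype=float)
        if np.any(c <= 0) or np.any((r <= 0) | (r > 1)):
            raise CostError("anchors need ratios in (0, 1] and positive costs")
        b = float(np.polyfit(r, np.log(c), 1)[0])
        if b < 0:
            raise CostError("anchor table implies a decreasing cost curve")
        r_cal, c_cal = calibration
        a = c_cal / math.exp(b * r_cal)
        return cls(a=a, b=b, calibration=(r_cal, c_cal))

    def unit_cost(self, reduction_ratio: float) -> float:
        """USD/kW at a given per-ship NOx reduction ratio in (0, 1]."""
        if not (0.0 < reduction_ratio <= 1.0):
            raise CostError("reduction ratio must lie in (0, 1]")
        return self.a * math.exp(self.b * reduction_ratio)


def nox_unit_cost(reduction_ratio: float,
                  curve: Optional[NoxCostCurve] = None) -> float:
    curve = curve or NoxCostCurve.from_anchors()
    return curve.unit_cost(reduction_ratio)


def neca_cost(total_kw: float, unit_cost: float) -> float:
    """Fleet retrofit cost: compliant installed power times unit cost."""
    if total_kw <= 0:
        raise CostError("fleet power must be positive")
    return total_kw * unit_cost


def policy_scenario_cost(scenario_id: str, zone: str,
                         premium: float = DEFAULT_PREMIUM,
                         fuel_tons: Optional[Dict[str, float]] = None,
                         fleet_kw: Optional[Dict[str, float]] = None,
                         tier3_ratio: float = TIER3_CALIBRATION[0],
                         curve: Optional[NoxCostCurve] = None) -> float:
    """Cost of one policy scenario: fuel premium for SECA, retrofit for NECA."""
    fuel_tons = fuel_tons or DEFAULT_FUEL_TONS
    fleet_kw = fleet_kw or DEFAULT_FLEET_KW
    if scenario_id.startswith("SECA"):
        if zone not in fuel_tons:
            raise CostError(f"no fuel consumption configured for zone {zone!r}")
        return fuel_switch_cost(consumption=fuel_tons[zone], premium=premium)
    if scenario_id.startswith("NECA"):
        if zone not in fleet_kw:
            raise CostError(f"no fleet power configured for zone {zone!r}")
        return neca_cost(fleet_kw[zone], nox_unit_cost(tier3_ratio, curve))
    raise CostError(f"unrecognized policy scenario {scenario_id!r}")


def policy_cost_benefit(costs: Dict[str, float],
                        benefits_usd: Dict[str, float]) -> pd.DataFrame:
    """Assemble the scenario cost vs monetized-health-benefit report.

    One row per scenario with cost, benefit, net benefit (= benefit - cost)
    and the benefit/cost ratio (infinity sentinel for zero-cost scenarios).
    Raises if the two inputs do not cover the same scenarios.
    """
    if set(costs) != set(benefits_usd):
        missing = set(costs) ^ set(benefits_usd)
        raise CostError(f"cost/benefit rows do not match: {sorted(missing)}")
    rows = []
    for sid in costs:
        cost, ben = float(costs[sid]), float(benefits_usd[sid])
        ratio = math.inf if cost == 0 else ben / cost
        rows.append({"scenario": sid, "cost_usd": cost, "benefit_usd": ben,
                     "net_benefit_usd": ben - cost, "benefit_cost_ratio": ratio})
    return pd.DataFrame(rows).set_index("scenario")
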