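"""Discounted program costs per screening strategy.

Costs cover first- and second-stage screening tests (per administration),
confirmatory laboratory testing of everyone referred, and per-person annual
programme overhead.  The national population is screened over a
``horizon_years`` implementation horizon with uniform annual throughput,
each year's spending discounted at ``discount_rate`` (year 0 undiscounted).
All totals are in millions of 2014 US dollars; cost per case found is total
cost divided by true-positive screens.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .screening_eval import ConfusionCounts
from .synthetic_inputs import UnitCosts, make_unit_costs

#: Unit-cost key charged per activity appearing in staged test counts.
ACTIVITY_COST_KEY = {
    "questionnaire": "questionnaire",
    "glucometer": "glucometer",
    "coin_flip": None,  # comparator, no materials cost
}


@dataclass
class CostModel:
    unit_costs: UnitCosts = field(default_factory=make_unit_costs)
    horizon_years: int = 10
    discount_rate: float = 0.03
    currency: str = "2014 US dollars"

    def __post_init__(self) -> None:
        if self.horizon_years < 1:
            raise ValueError("horizon_years must be >= 1")
        if not 0.0 <= self.discount_rate < 1.0:
            raise ValueError("discount_rate must be in [0, 1)")


@dataclass
class CostSummary:
    """Discounted cost totals (millions) and cost per case found (dollars)."""

    total_cost: float
    cost_per_case_found: float  # NaN marker when no true positives
    components: Mapping[str, float]

    def __post_init__(self) -> None:
        if abs(self.total_cost - sum(self.components.values())) > 1e-9 * max(
            1.0, abs(self.total_cost)
        ):
            raise ValueError("total_cost must equal the sum of components")


def discount_factor(horizon_years: int, rate: float) -> float:
    """Sum of (1+rate)^-t over years t = 0 .. horizon-1."""
    if horizon_years < 1:
        raise ValueError("horizon_years must be >= 1")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    return sum((1.0 + rate) ** -t for t in range(horizon_years))


def cost_per_case(total_cost_millions: float, tp_millions: float) -> float:
    """Dollars per true-positive case found; NaN marker when TP is zero."""
    if tp_millions <= 0:
        return math.nan
    return total_cost_millions / tp_millions


def cost_strategy(
    counts: ConfusionCounts,
    staged_tests_millions: Mapping[str, float],
    model: CostModel,
) -> CostSummary:
    """Discounted cost of one screening strategy.

    ``staged_tests_millions`` maps each screening activity to the weighted
    millions of tests administered (a serial second stage only counts
    first-stage positives).  Confirmatory testing is charged for everyone
    referred; overhead accrues per person screened per programme year.
    """
    unit = model.unit_costs
    df_per_year = discount_factor(model.horizon_years, model.discount_rate) / model.horizon_years

    screening = 0.0
    for activity, n_millions in staged_tests_millions.items():
        if activity not in ACTIVITY_COST_KEY:
            raise ValueError(f"no unit cost configured for activity {activity!r}")
        key = ACTIVITY_COST_KEY[activity]
        if key is not None:
            screening += getattr(unit, key) * n_millions
    confirmatory = unit.confirmatory_lab * counts.referred_total
    overhead = unit.overhead_per_person_year * counts.eligible_total

    components = {
        "screening": screening * df_per_year,
        "confirmatory": confirmatory * df_per_year,
        "overhead": overhead * df_per_year,
    }
    total = sum(components.values())
    return CostSummary(
        total_cost=total,
        cost_per_case_found=cost_per_case(total, counts.tp),
        components=components,
    )
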