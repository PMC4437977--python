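"""Apply screening strategies to the weighted population and tally results.

Confusion counts are weight sums in millions of persons at national scale.
The target condition ("case") is previously undiagnosed diabetes as it would
be confirmed downstream: fasting plasma glucose >= 7.0 mmol/l among persons
not already carrying a diagnosis.  Sensitivity, specificity, predictive
values and the number needed to screen (NNS = eligible screened per true
positive) follow from the weighted counts.

Undefined ratios (NNS or the false:true ratio when no true positives exist)
are reported as NaN markers, never raised.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .instruments import ScreeningStrategy, ScreenOutcome, confirmatory_test
from .population import PopulationSample
from .strata import StratumKey, all_strata

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    """Weighted screen-vs-truth cross-tabulation, millions of persons."""

    tp: float
    fp: float
    tn: float
    fn: float

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def eligible_total(self) -> float:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def referred_total(self) -> float:
        return self.tp + self.fp

    @property
    def cases_total(self) -> float:
        return self.tp + self.fn


@dataclass
class ScreeningMetrics:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    nns: float  # NaN when undefined (no true positives)

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            v = getattr(self, name)
            if not (math.isnan(v) or 0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")


def metrics_from_counts(counts: ConfusionCounts) -> ScreeningMetrics:
    """Derive the diagnostic metrics from weighted confusion counts."""

    def _ratio(num: float, den: float) -> float:
        return num / den if den > 0 else math.nan

    return ScreeningMetrics(
        sensitivity=_ratio(counts.tp, counts.tp + counts.fn),
        specificity=_ratio(counts.tn, counts.tn + counts.fp),
        ppv=_ratio(counts.tp, counts.tp + counts.fp),
        npv=_ratio(counts.tn, counts.tn + counts.fn),
        nns=_ratio(counts.eligible_total, counts.tp) if counts.tp > 0 else math.nan,
    )


def number_needed_to_screen(eligible_millions: float, tp_millions: float) -> float:
    """NNS = persons screened per undiagnosed case detected (NaN if none)."""
    if tp_millions <= 0:
        return math.nan
    return eligible_millions / tp_millions


def false_true_ratio(counts: ConfusionCounts) -> float:
    """False positives per true positive; NaN marker when TP is zero."""
    if counts.tp <= 0:
        return math.nan if counts.fp > 0 else 0.0
    return counts.fp / counts.tp


def _case_mask(df: pd.DataFrame) -> np.ndarray:
    # undiagnosed diabetes per the confirmatory fasting criterion
    return np.asarray(confirmatory_test(df)) & (~df["previously_diagnosed"].to_numpy())


def _counts_from_outcome(df: pd.DataFrame, positive: np.ndarray) -> ConfusionCounts:
    case = _case_mask(df)
    w = df["weight"].to_numpy(dtype=float)
    return ConfusionCounts(
        tp=float(w[positive & case].sum()),
        fp=float(w[positive & ~case].sum()),
        tn=float(w[~positive & ~case].sum()),
        fn=float(w[~positive & case].sum()),
    )


def evaluate_strategy(
    pop: PopulationSample,
    strategy: ScreeningStrategy,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> tuple[ConfusionCounts, ScreeningMetrics, ScreenOutcome]:
    """Screen the eligible population once and tally weighted outcomes."""
    if len(pop) == 0:
        raise ValueError("population is empty")
    df = pop.frame
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    outcome = strategy.apply(df, rng)
    counts = _counts_from_outcome(df, outcome.positive)
    return counts, metrics_from_counts(counts), outcome


def staged_test_millions(df: pd.DataFrame, outcome: ScreenOutcome) -> dict[str, float]:
    """Weighted millions of tests administered per screening activity."""
    w = df["weight"].to_numpy(dtype=float)
    staged: dict[str, float] = {}
    for activity, mask in outcome.stages:
        staged[activity] = staged.get(activity, 0.0) + float(w[mask].sum())
    return staged


def direct_fasting_comparator(
    pop: PopulationSample,
) -> tuple[ConfusionCounts, ScreeningMetrics]:
    """Everyone goes straight to the laboratory fasting test.

    The fasting test is also the diagnostic criterion, so sensitivity and
    specificity are 1 by construction and the NNS equals eligible persons per
    undiagnosed case.
    """
    if len(pop) == 0:
        raise ValueError("population is empty")
    df = pop.frame
    positive = np.asarray(confirmatory_test(df))
    counts = _counts_from_outcome(df, positive)
    return counts, metrics_from_counts(counts)


def targeted_screening(
    pop: PopulationSample,
    strategy: ScreeningStrategy,
    subgroup: Callable[[StratumKey], bool],
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> tuple[ConfusionCounts, ScreeningMetrics, float] | None:
    """Evaluate a strategy restricted to the strata matched by ``subgroup``.

    Returns (counts, metrics, false:true ratio), or None (with a log entry)
    when no person falls in the subgroup.
    """
    selected = {k for k in all_strata() if subgroup(k)}
    df = pop.frame
    mask = np.array(
        [
            StratumKey(a, s, l, i) in selected
            for a, s, l, i in zip(
                df["age_band"], df["sex"], df["location"], df["income"]
            )
        ],
        dtype=bool,
    )
    if not mask.any():
        logger.info("targeted screening: empty subgroup, skipped")
        return None
    sub = PopulationSample(df[mask].copy())
    counts, metrics, _ = evaluate_strategy(sub, strategy, seed)
    return counts, metrics, false_true_ratio(counts)


def comorbidity_codetection(
    pop: PopulationSample,
    strategy: ScreeningStrategy,
    seed: int | np.random.SeedSequence | np.random.Generator,
    *,
    outcome: ScreenOutcome | None = None,
) -> dict[str, float]:
    """Fractions of screen-positive persons with hypertension and obesity.

    Hypertension is systolic >= 140 or diastolic >= 90 mm Hg; obesity is
    BMI >= 30 kg/m^2.  Weighted; NaN if nobody screens positive.
    """
    df = pop.frame
    if outcome is None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        outcome = strategy.apply(df, rng)
    w = df["weight"].to_numpy(dtype=float)
    pos = outcome.positive
    w_pos = w[pos].sum()
    if w_pos == 0:
        return {"hypertension": math.nan, "obesity": math.nan}
    htn = (df["systolic_bp"].to_numpy() >= 140) | (df["diastolic_bp"].to_numpy() >= 90)
    obese = df["bmi"].to_numpy() >= 30
    return {
        "hypertension": float(w[pos & htn].sum() / w_pos),
        "obesity": float(w[pos & obese].sum() / w_pos),
    }
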