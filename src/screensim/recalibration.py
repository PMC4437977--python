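"""ROC curves over instrument thresholds and cut-point recalibration.

Cut points published for sub-national cohorts need not be optimal for the
national population; the recalibration sweeps every achievable threshold,
computes weighted sensitivity and specificity against the undiagnosed-
diabetes truth, and picks the threshold maximising sensitivity x
specificity (the top-left-most ROC corner), breaking ties toward higher
specificity to minimise confirmatory-testing burden.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .instruments import GlucometerSpec, InstrumentSpec
from .population import PopulationSample
from .screening_eval import _case_mask


@dataclass
class RocPoint:
    threshold: float
    sensitivity: float
    specificity: float


@dataclass
class RocCurve:
    points: list[RocPoint]  # ordered by increasing threshold
    auc: float

    def __post_init__(self) -> None:
        sens = [p.sensitivity for p in self.points]
        spec = [p.specificity for p in self.points]
        if any(b > a + 1e-12 for a, b in zip(sens, sens[1:])):
            raise ValueError("sensitivity must be non-increasing in threshold")
        if any(b < a - 1e-12 for a, b in zip(spec, spec[1:])):
            raise ValueError("specificity must be non-decreasing in threshold")


def roc_from_scores(
    value: np.ndarray,
    case: np.ndarray,
    weight: np.ndarray,
    thresholds: Sequence[float],
) -> RocCurve:
    """Weighted ROC at the given thresholds (positive at value >= t)."""
    w_case = float(weight[case].sum())
    w_non = float(weight[~case].sum())
    if w_case == 0 or w_non == 0:
        raise ValueError("ROC needs both cases and non-cases in the population")
    points = []
    for t in sorted(thresholds):
        pos = value >= t
        sens = float(weight[pos & case].sum()) / w_case
        spec = float(weight[~pos & ~case].sum()) / w_non
        points.append(RocPoint(threshold=float(t), sensitivity=sens, specificity=spec))
    fpr = np.array([1.0 - p.specificity for p in points])
    tpr = np.array([p.sensitivity for p in points])
    order = np.argsort(fpr)
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    return RocCurve(points=points, auc=auc)


def roc_sweep(
    pop: PopulationSample,
    spec: InstrumentSpec | GlucometerSpec,
    seed: int | np.random.Generator = 0,
    *,
    glucometer_step: float = 0.1,
) -> RocCurve:
    """ROC over all achievable thresholds for an instrument or glucometer.

    Questionnaire scores sweep every achievable integer score; glucometer
    measurements (with fresh device error) sweep a configured grid.  A
    threshold below and above the observed range supplies the (1,0) and
    (0,1) endpoints.
    """
    df = pop.frame
    case = _case_mask(df)
    weight = df["weight"].to_numpy(dtype=float)
    if isinstance(spec, InstrumentSpec):
        value = spec.score(df).astype(float)
        achievable = spec.enumerate_scores()
        thresholds = [achievable[0] - 1.0] + [float(s) for s in achievable] + [
            achievable[-1] + 1.0
        ]
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        value = df["random_glucose_true"].to_numpy(dtype=float)
        value = value + spec.meter_error_sd * rng.standard_normal(len(df))
        lo = np.floor(value.min() / glucometer_step) * glucometer_step
        hi = np.ceil(value.max() / glucometer_step) * glucometer_step
        thresholds = list(
            np.round(np.arange(lo - glucometer_step, hi + 2 * glucometer_step, glucometer_step), 10)
        )
    return roc_from_scores(value, case, weight, thresholds)


def recalibrate_cutpoint(curve: RocCurve) -> float:
    """Threshold maximising sensitivity x specificity.

    Ties go to the higher-specificity (higher-threshold) point, which refers
    fewer people for confirmatory testing.
    """
    if not curve.points:
        raise ValueError("empty ROC curve")
    best = None
    best_product = -1.0
    for p in curve.points:
        product = p.sensitivity * p.specificity
        if product > best_product + 1e-15 or (
            abs(product - best_product) <= 1e-15
            and best is not None
            and p.specificity > best.specificity
        ):
            best = p
            best_product = product
    assert best is not None
    return best.threshold
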