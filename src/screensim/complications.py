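"""Long-term complication risks among screen-detected diabetes cases.

Complication endpoints (heart disease events, stroke, blindness, diabetic
ulcer, renal failure) are evaluated over a 20-year horizon through a
pluggable risk-equation interface: any set of per-endpoint functions mapping
a biomarker profile to a probability can be supplied (for example published
outcome-model equations).  The shipped default is a documented parametric
logistic form, monotone non-decreasing in every hazard-raising biomarker:

    risk = expit(b0 + sum_k c_k * (x_k - center_k) / scale_k),  c_k >= 0.

Best-case treatment clamps systolic blood pressure, LDL cholesterol and
HbA1c down to guideline targets (never raising a value already at goal);
the number needed to screen and treat (NNST) per endpoint is the reciprocal
of the weighted mean absolute risk reduction among detected cases.  The
probability of any complication assumes conditional independence of
endpoints given the profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .costs import CostSummary
from .population import RiskFactorProfile

ENDPOINTS = ("heart_disease", "stroke", "blindness", "ulcer", "renal_failure")

#: Biomarker transforms used by the default equations: (column, center, scale).
_BIOMARKER_TERMS = {
    "sbp_per_10": ("systolic_bp", 120.0, 10.0),
    "ldl_per_1": ("ldl", 2.6, 1.0),
    "hba1c_per_1": ("hba1c", 6.5, 1.0),
    "age_per_10": ("age", 50.0, 10.0),
    "smoker": ("smoker", 0.0, 1.0),
}


@dataclass(frozen=True)
class TreatmentTargets:
    """Best-case guideline treatment goals."""

    sbp_target: float = 140.0  # mm Hg
    ldl_target: float = 2.6  # mmol/l, no cardiovascular history
    ldl_target_cvd: float = 1.8  # mmol/l, with cardiovascular history
    hba1c_target: float = 7.0  # percent

    def __post_init__(self) -> None:
        for name in ("sbp_target", "ldl_target", "ldl_target_cvd", "hba1c_target"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class RiskEquation:
    """Logistic 20-year risk for one endpoint; coefficients must be >= 0."""

    endpoint: str
    baseline_risk: float  # risk with every biomarker at its center
    coefficients: Mapping[str, float]

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_risk < 1.0:
            raise ValueError("baseline_risk must be in (0,1)")
        for term, c in self.coefficients.items():
            if term not in _BIOMARKER_TERMS:
                raise ValueError(f"unknown biomarker term {term!r}")
            if c < 0:
                raise ValueError(
                    f"{self.endpoint}: coefficient for {term} must be >= 0 "
                    "(risk monotone in hazard-raising biomarkers)"
                )

    def risk(self, df: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(df), logit(self.baseline_risk))
        for term, c in self.coefficients.items():
            column, center, scale = _BIOMARKER_TERMS[term]
            if column not in df.columns:
                raise ValueError(f"profile lacks biomarker {column!r}")
            x = df[column].to_numpy(dtype=float)
            eta = eta + c * (x - center) / scale
        return expit(eta)


@dataclass
class RiskEquationSet:
    equations: Mapping[str, RiskEquation]
    provenance: str = "parametric default"

    def __post_init__(self) -> None:
        for name, eq in self.equations.items():
            if eq.endpoint != name:
                raise ValueError(f"endpoint mismatch: {name} vs {eq.endpoint}")


def default_risk_equations() -> RiskEquationSet:
    """Documented parametric defaults: macrovascular endpoints driven mainly
    by blood pressure, LDL, smoking and age; microvascular endpoints by
    glycaemia."""
    eqs = {
        "heart_disease": RiskEquation(
            "heart_disease", 0.20,
            {"sbp_per_10": 0.15, "ldl_per_1": 0.25, "hba1c_per_1": 0.10,
             "age_per_10": 0.30, "smoker": 0.40},
        ),
        "stroke": RiskEquation(
            "stroke", 0.08,
            {"sbp_per_10": 0.25, "ldl_per_1": 0.10, "hba1c_per_1": 0.08,
             "age_per_10": 0.35, "smoker": 0.30},
        ),
        "blindness": RiskEquation(
            "blindness", 0.04,
            {"hba1c_per_1": 0.35, "sbp_per_10": 0.05, "age_per_10": 0.15},
        ),
        "ulcer": RiskEquation(
            "ulcer", 0.05,
            {"hba1c_per_1": 0.30, "age_per_10": 0.10, "smoker": 0.15},
        ),
        "renal_failure": RiskEquation(
            "renal_failure", 0.03,
            {"hba1c_per_1": 0.30, "sbp_per_10": 0.15, "age_per_10": 0.10},
        ),
    }
    return RiskEquationSet(eqs)


@dataclass
class NNSTResult:
    """Absolute risk reductions and NNST per endpoint and overall."""

    arr: Mapping[str, float]  # endpoint -> weighted mean risk reduction
    nnst: Mapping[str, float]  # endpoint -> 1/ARR, NaN when ARR <= 0
    fraction_avoiding_any: float
    nnst_any: float  # 1 / fraction avoiding any complication
    min_nnst_endpoint: str  # endpoint with the smallest (best) defined NNST


def apply_treatment(profile_or_df, targets: TreatmentTargets):
    """Clamp treated biomarkers down to targets; never raise a value.

    Accepts a single :class:`RiskFactorProfile` or a person DataFrame;
    returns the same kind, treated.
    """
    if isinstance(profile_or_df, pd.DataFrame):
        df = profile_or_df.copy()
        ldl_target = np.where(
            df["cvd_history"].to_numpy(dtype=bool),
            targets.ldl_target_cvd,
            targets.ldl_target,
        )
        df["systolic_bp"] = np.minimum(df["systolic_bp"], targets.sbp_target)
        df["ldl"] = np.minimum(df["ldl"], ldl_target)
        df["hba1c"] = np.minimum(df["hba1c"], targets.hba1c_target)
        return df
    p: RiskFactorProfile = profile_or_df
    ldl_target = targets.ldl_target_cvd if p.cvd_history else targets.ldl_target
    return replace(
        p,
        systolic_bp=min(p.systolic_bp, targets.sbp_target),
        ldl=min(p.ldl, ldl_target),
        hba1c=min(p.hba1c, targets.hba1c_target),
    )


def complication_risk(eqs: RiskEquationSet, profile_or_df) -> dict[str, np.ndarray] | dict[str, float]:
    """20-year risk per endpoint for a profile or a person table."""
    if isinstance(profile_or_df, pd.DataFrame):
        return {name: eq.risk(profile_or_df) for name, eq in eqs.equations.items()}
    from .instruments import _profile_frame

    df = _profile_frame(profile_or_df, sex="male")
    return {name: float(eq.risk(df)[0]) for name, eq in eqs.equations.items()}


def any_complication_probability(risks: Mapping[str, np.ndarray]) -> np.ndarray:
    """P(at least one endpoint), endpoints conditionally independent."""
    none = np.ones_like(next(iter(risks.values())))
    for r in risks.values():
        none = none * (1.0 - np.asarray(r))
    return 1.0 - none


def nnst(
    detected: pd.DataFrame,
    eqs: RiskEquationSet,
    targets: TreatmentTargets,
) -> NNSTResult:
    """NNST among screen-detected cases under best-case treatment.

    ``detected`` is the person table of true-positive screens (must carry
    ``weight``).  ARR per endpoint is the weighted mean of untreated minus
    treated risk; NNST is its reciprocal.
    """
    if len(detected) == 0:
        raise ValueError("no detected cases")
    w = detected["weight"].to_numpy(dtype=float)
    w = w / w.sum()
    treated = apply_treatment(detected, targets)
    risk_untreated = complication_risk(eqs, detected)
    risk_treated = complication_risk(eqs, treated)

    arr: dict[str, float] = {}
    nnst_map: dict[str, float] = {}
    for endpoint in eqs.equations:
        delta = float(np.sum(w * (risk_untreated[endpoint] - risk_treated[endpoint])))
        arr[endpoint] = delta
        nnst_map[endpoint] = 1.0 / delta if delta > 0 else math.nan

    any_u = any_complication_probability(risk_untreated)
    any_t = any_complication_probability(risk_treated)
    fraction = float(np.sum(w * (any_u - any_t)))
    defined = {e: v for e, v in nnst_map.items() if not math.isnan(v)}
    return NNSTResult(
        arr=arr,
        nnst=nnst_map,
        fraction_avoiding_any=fraction,
        nnst_any=1.0 / fraction if fraction > 0 else math.nan,
        min_nnst_endpoint=min(defined, key=defined.get) if defined else "",
    )


def cost_per_complication_prevented(cost: CostSummary, result: NNSTResult) -> float:
    """Screening dollars per detected case whose complication is averted.

    Equals total cost / (true positives x fraction avoiding any
    complication) = cost per case found / fraction; NaN marker when the
    treatment effect is nil.
    """
    if not result.fraction_avoiding_any > 0:
        return math.nan
    return cost.cost_per_case_found / result.fraction_avoiding_any
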