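"""Synthetic national population for the screening microsimulation.

Rather than simulating 567 million agents, a sample of ``n_persons``
individuals is drawn, each carrying a national sampling weight (millions of
persons represented = stratum population / stratum sample count).  Each
person gets a stratum, a diabetes status (Bernoulli at the stratum
prevalence), a diagnosis status (Bernoulli at the stratum probability of
being undiagnosed given diabetes), and a correlated risk-factor profile
drawn from a status-conditional Gaussian copula.

The person table is a pandas DataFrame — one row per person, one column per
field — which keeps instrument scoring and confusion-count aggregation
vectorised.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, fields as dc_fields
from typing import Mapping

import numpy as np
import pandas as pd

from .meta_regression import PrevalenceSurface
from .strata import AGE_RANGES, DemographicTable, StratumKey, all_strata
from .synthetic_inputs import (
    CONTINUOUS_FACTORS,
    FAMILY_HISTORY_LEVELS,
    LOG_SCALE_FACTORS,
    PHYSICAL_ACTIVITY_LEVELS,
    RiskFactorParams,
)

logger = logging.getLogger(__name__)

STRATUM_COLUMNS = ("age_band", "sex", "location", "income")

PROFILE_COLUMNS = (
    "age", "systolic_bp", "diastolic_bp", "bmi", "waist",
    "family_history", "physical_activity",
    "random_glucose_true", "fasting_glucose_true", "hba1c", "ldl",
    "smoker", "cvd_history",
)

#: Prevalence of a prior cardiovascular event, status-conditional; only used
#: by the LDL treatment-target rule.
CVD_HISTORY_PROB = {"nondiabetic": 0.02, "diabetic": 0.06}


@dataclass
class RiskFactorProfile:
    """One person's risk factors and biomarkers."""

    age: float
    systolic_bp: float
    diastolic_bp: float
    bmi: float
    waist: float
    family_history: str
    physical_activity: str
    random_glucose_true: float
    fasting_glucose_true: float
    hba1c: float
    ldl: float
    smoker: bool
    cvd_history: bool = False

    def __post_init__(self) -> None:
        for name in ("age", "systolic_bp", "diastolic_bp", "bmi", "waist",
                     "random_glucose_true", "fasting_glucose_true", "hba1c", "ldl"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v}")
        if self.family_history not in FAMILY_HISTORY_LEVELS:
            raise ValueError(f"unknown family_history {self.family_history!r}")
        if self.physical_activity not in PHYSICAL_ACTIVITY_LEVELS:
            raise ValueError(f"unknown physical_activity {self.physical_activity!r}")


@dataclass
class Person:
    stratum: StratumKey
    has_diabetes: bool
    previously_diagnosed: bool
    profile: RiskFactorProfile
    weight: float  # millions of persons represented

    def __post_init__(self) -> None:
        if self.previously_diagnosed and not self.has_diabetes:
            raise ValueError("previously_diagnosed requires has_diabetes")
        if self.weight <= 0:
            raise ValueError("weight must be > 0")


class PopulationSample:
    """Weighted person table plus bookkeeping totals."""

    def __init__(self, frame: pd.DataFrame, demographic_total: float | None = None):
        required = set(STRATUM_COLUMNS) | set(PROFILE_COLUMNS) | {
            "has_diabetes", "previously_diagnosed", "weight", "sex",
        }
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"population frame missing columns: {sorted(missing)}")
        bad = frame["previously_diagnosed"] & ~frame["has_diabetes"]
        if bad.any():
            raise ValueError("previously_diagnosed person without diabetes")
        if (frame["weight"] <= 0).any():
            raise ValueError("all person weights must be > 0")
        self.frame = frame.reset_index(drop=True)
        self.demographic_total = demographic_total
        if demographic_total is not None:
            tot = float(frame["weight"].sum())
            if abs(tot - demographic_total) > 1e-6 * max(demographic_total, 1.0):
                raise ValueError(
                    f"weights sum to {tot}, expected {demographic_total}"
                )

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def total_weight(self) -> float:
        return float(self.frame["weight"].sum())

    @property
    def eligible_mask(self) -> np.ndarray:
        return (~self.frame["previously_diagnosed"]).to_numpy()

    def eligible_subset(self) -> "PopulationSample":
        return PopulationSample(self.frame[self.eligible_mask].copy())

    def stratum_totals(self) -> pd.DataFrame:
        return (
            self.frame.groupby(list(STRATUM_COLUMNS), observed=True)["weight"]
            .sum()
            .reset_index()
        )

    def person(self, i: int) -> Person:
        row = self.frame.iloc[i]
        profile = RiskFactorProfile(
            **{f.name: row[f.name] for f in dc_fields(RiskFactorProfile)}
        )
        return Person(
            stratum=StratumKey(row.age_band, row.sex, row.location, row.income),
            has_diabetes=bool(row.has_diabetes),
            previously_diagnosed=bool(row.previously_diagnosed),
            profile=profile,
            weight=float(row.weight),
        )

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def eligible_subset(pop: PopulationSample) -> PopulationSample:
    """Persons not previously diagnosed; per-person weights unchanged."""
    return pop.eligible_subset()


def _draw_continuous_block(
    n: int, status: str, params: RiskFactorParams, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Gaussian-copula draw of the continuous factors for one status group."""
    if n == 0:
        return {f: np.empty(0) for f in CONTINUOUS_FACTORS}
    chol = np.linalg.cholesky(
        params.correlation + 1e-12 * np.eye(len(CONTINUOUS_FACTORS))
    )
    z = rng.standard_normal((n, len(CONTINUOUS_FACTORS))) @ chol.T
    out: dict[str, np.ndarray] = {}
    for i, factor in enumerate(CONTINUOUS_FACTORS):
        mu = params.means[status][factor]
        sd = params.sds[status][factor]
        if factor in LOG_SCALE_FACTORS:
            out[factor] = np.exp(np.log(mu) + sd * z[:, i])
        else:
            # floor guards the positivity invariant in extreme tails
            out[factor] = np.maximum(mu + sd * z[:, i], 1e-3)
    return out


def _draw_categoricals(
    n: int, status: str, params: RiskFactorParams, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Status-conditional categorical draws, as integer level codes."""
    fh = rng.choice(
        len(FAMILY_HISTORY_LEVELS), size=n, p=params.family_history_probs[status]
    )
    pa = rng.choice(
        len(PHYSICAL_ACTIVITY_LEVELS), size=n, p=params.physical_activity_probs[status]
    )
    smoker = rng.random(n) < params.smoker_prob[status]
    cvd = rng.random(n) < CVD_HISTORY_PROB[status]
    return {"family_history": fh, "physical_activity": pa, "smoker": smoker,
            "cvd_history": cvd}


def draw_profile(
    has_diabetes: bool,
    stratum: StratumKey,
    dist_params: RiskFactorParams,
    rng: np.random.Generator,
) -> RiskFactorProfile:
    """Draw one status- and stratum-conditional risk-factor profile."""
    status = "diabetic" if has_diabetes else "nondiabetic"
    cont = _draw_continuous_block(1, status, dist_params, rng)
    cat = _draw_categoricals(1, status, dist_params, rng)
    lo, hi = AGE_RANGES[stratum.age_band]
    age = float(rng.uniform(lo, hi))
    return RiskFactorProfile(
        age=age,
        systolic_bp=float(cont["systolic_bp"][0]),
        diastolic_bp=float(cont["diastolic_bp"][0]),
        bmi=float(cont["bmi"][0]),
        waist=float(cont["waist"][0]),
        family_history=FAMILY_HISTORY_LEVELS[int(cat["family_history"][0])],
        physical_activity=PHYSICAL_ACTIVITY_LEVELS[int(cat["physical_activity"][0])],
        random_glucose_true=float(cont["random_glucose_true"][0]),
        fasting_glucose_true=float(cont["fasting_glucose_true"][0]),
        hba1c=float(cont["hba1c"][0]),
        ldl=float(cont["ldl"][0]),
        smoker=bool(cat["smoker"][0]),
        cvd_history=bool(cat["cvd_history"][0]),
    )


def build_population(
    demo: DemographicTable,
    surface: PrevalenceSurface,
    dist_params: RiskFactorParams,
    n_persons: int,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> PopulationSample:
    """Simulate the weighted national population sample.

    Persons are allocated to strata by a multinomial draw on the demographic
    shares; per-person weight is stratum millions divided by the stratum's
    realised sample count, so weights always sum exactly to the national
    total.
    """
    if n_persons < 24:
        raise ValueError("n_persons must be at least 24 (one per stratum expected)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    strata = all_strata()
    shares = np.array([demo.shares()[k] for k in strata])

    counts = None
    for attempt in range(3):
        trial = rng.multinomial(n_persons, shares)
        empty = [k for k, c, s in zip(strata, trial, shares) if c == 0 and s > 0]
        if not empty:
            counts = trial
            break
        warnings.warn(
            f"attempt {attempt + 1}: {len(empty)} nonzero-weight strata drew no "
            "persons; resampling allocation"
        )
    if counts is None:
        raise RuntimeError(
            "could not allocate at least one person to every nonzero-weight "
            "stratum; increase n_persons"
        )

    stratum_idx = np.repeat(np.arange(len(strata)), counts)
    n = len(stratum_idx)

    def _stratum_categorical(attr: str, levels: tuple[str, ...]) -> pd.Categorical:
        codes = np.array([levels.index(getattr(k, attr)) for k in strata])
        return pd.Categorical.from_codes(codes[stratum_idx], categories=list(levels))

    from .strata import AGE_BANDS, INCOMES, LOCATIONS, SEXES

    age_band = _stratum_categorical("age_band", AGE_BANDS)
    sex = _stratum_categorical("sex", SEXES)
    location = _stratum_categorical("location", LOCATIONS)
    income = _stratum_categorical("income", INCOMES)

    prev = np.array([surface.probability("prevalence_total", k) for k in strata])
    undiag = np.array(
        [surface.probability("undiagnosed_given_diabetes", k) for k in strata]
    )
    has_diabetes = rng.random(n) < prev[stratum_idx]
    diagnosed = np.zeros(n, dtype=bool)
    diabetic = has_diabetes.nonzero()[0]
    diagnosed[diabetic] = rng.random(len(diabetic)) >= undiag[stratum_idx[diabetic]]

    weight_per_person = np.zeros(n)
    w = np.array([demo.weights[k] for k in strata], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_stratum_weight = np.where(counts > 0, w / np.maximum(counts, 1), 0.0)
    weight_per_person = per_stratum_weight[stratum_idx]

    # status-conditional profile draws, scattered back into person order
    columns: dict[str, np.ndarray] = {
        c: np.empty(n, dtype=np.int8) for c in ("family_history", "physical_activity")
    }
    for c in CONTINUOUS_FACTORS:
        columns[c] = np.empty(n)
    columns["smoker"] = np.empty(n, dtype=bool)
    columns["cvd_history"] = np.empty(n, dtype=bool)
    for status, mask in (("diabetic", has_diabetes), ("nondiabetic", ~has_diabetes)):
        idx = mask.nonzero()[0]
        cont = _draw_continuous_block(len(idx), status, dist_params, rng)
        cat = _draw_categoricals(len(idx), status, dist_params, rng)
        for c in CONTINUOUS_FACTORS:
            columns[c][idx] = cont[c]
        for c in ("family_history", "physical_activity", "smoker", "cvd_history"):
            columns[c][idx] = cat[c]

    young = np.asarray(age_band == "25-44")
    lo = np.where(young, AGE_RANGES["25-44"][0], AGE_RANGES["45-65"][0])
    hi = np.where(young, AGE_RANGES["25-44"][1], AGE_RANGES["45-65"][1])
    age = rng.uniform(lo, hi)

    frame = pd.DataFrame(
        {
            "age_band": age_band, "sex": sex, "location": location, "income": income,
            "has_diabetes": has_diabetes, "previously_diagnosed": diagnosed,
            "weight": weight_per_person, "age": age,
            **{c: columns[c] for c in CONTINUOUS_FACTORS},
            "family_history": pd.Categorical.from_codes(
                columns["family_history"], categories=list(FAMILY_HISTORY_LEVELS)
            ),
            "physical_activity": pd.Categorical.from_codes(
                columns["physical_activity"], categories=list(PHYSICAL_ACTIVITY_LEVELS)
            ),
            "smoker": columns["smoker"],
            "cvd_history": columns["cvd_history"],
        }
    )
    return PopulationSample(frame, demographic_total=demo.total_population)
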