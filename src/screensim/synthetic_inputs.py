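"""Synthetic model inputs with known ground truth.

The national evidence base behind the screening model — a table of published
cohort-study summaries, the joint risk-factor distributions, and the unit
costs — is emulated here by generators with fully known parameters, so every
downstream stage (meta-regression recovery, population synthesis, screening
arithmetic) can be tested against the truth that produced its inputs.

The cohort-study generator draws, for each simulated study,

* moderator shares (age, sex, location, income composition) from Dirichlet
  mixing distributions,
* a true outcome proportion from the linear predictor of the ground-truth
  coefficients plus a Normal between-study effect, and
* an observed proportion with binomial sampling noise at the study's n,
  recording the usual p(1-p)/n sampling variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .strata import DEFAULT_MARGINALS, StratumKey

logger = logging.getLogger(__name__)

#: Moderator (dummy) columns of the prevalence model; the reference category
#: in each family (age 25-44, female, rural, low income) is dropped.
MODERATORS = ("age_45_65", "male", "urban", "income_mid", "income_high")

#: Outcomes modelled by meta-regression.
OUTCOMES = ("prevalence_total", "undiagnosed_given_diabetes", "hypertension", "obesity")

#: Calendar year at which the year covariate is centred.
YEAR_REF = 2015

#: Share columns recorded per study (all categories, both reference and not).
SHARE_COLUMNS = (
    "age_25_44", "age_45_65",
    "female", "male",
    "rural", "urban",
    "income_low", "income_mid", "income_high",
)

_SHARE_FAMILIES = {
    "age": ("age_25_44", "age_45_65"),
    "sex": ("female", "male"),
    "location": ("rural", "urban"),
    "income": ("income_low", "income_mid", "income_high"),
}

CONTINUOUS_FACTORS = (
    "systolic_bp", "diastolic_bp", "bmi", "waist",
    "random_glucose_true", "fasting_glucose_true", "hba1c", "ldl",
)

#: Factors modelled log-Normally (positive, right-skewed biomarkers).
LOG_SCALE_FACTORS = frozenset(
    {"random_glucose_true", "fasting_glucose_true", "hba1c"}
)

FAMILY_HISTORY_LEVELS = ("none", "one_parent_or_sibling", "both_parents")
PHYSICAL_ACTIVITY_LEVELS = (
    "regular_exercise_and_strenuous_work", "one_of_the_two", "neither",
)


@dataclass
class RiskFactorParams:
    """Status-conditional joint distribution of the risk-factor profile.

    Continuous factors follow a Gaussian copula: Normal marginals on the raw
    scale, log-Normal for the glucose/HbA1c block, tied by a single
    correlation matrix.  ``means``/``sds`` are given on the *natural* scale
    (log-scale factors: median and log-SD).  Categorical factors are drawn
    independently from status-conditional probabilities.
    """

    means: Mapping[str, Mapping[str, float]]  # status -> factor -> value
    sds: Mapping[str, Mapping[str, float]]
    correlation: np.ndarray  # shared across statuses, CONTINUOUS_FACTORS order
    family_history_probs: Mapping[str, Sequence[float]]
    physical_activity_probs: Mapping[str, Sequence[float]]
    smoker_prob: Mapping[str, float]

    def __post_init__(self) -> None:
        c = np.asarray(self.correlation, dtype=float)
        k = len(CONTINUOUS_FACTORS)
        if c.shape != (k, k):
            raise ValueError(f"correlation must be {k}x{k}")
        if not np.allclose(c, c.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-12):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(c).min() < -1e-10:
            raise ValueError("correlation matrix must be positive semi-definite")
        self.correlation = c
        for probs in (self.family_history_probs, self.physical_activity_probs):
            for status, p in probs.items():
                if abs(sum(p) - 1.0) > 1e-9 or min(p) < 0:
                    raise ValueError(f"invalid categorical probabilities for {status}")


@dataclass
class GroundTruth:
    """True parameters behind all synthetic inputs.

    ``coefficients``: per outcome, the linear-predictor coefficients
    (``intercept``, one per moderator, ``year``) on ``scale``.
    """

    coefficients: Mapping[str, Mapping[str, float]]
    scale: str = "logit"
    risk_factors: RiskFactorParams | None = None
    year_ref: int = YEAR_REF

    def __post_init__(self) -> None:
        if self.scale not in ("logit", "linear"):
            raise ValueError("scale must be 'logit' or 'linear'")
        for outcome, coefs in self.coefficients.items():
            if "intercept" not in coefs:
                raise ValueError(f"{outcome}: missing intercept")

    def linear_predictor(self, outcome: str, x: Mapping[str, float], year: float) -> float:
        coefs = self.coefficients[outcome]
        eta = coefs["intercept"] + coefs.get("year", 0.0) * (year - self.year_ref)
        for m in MODERATORS:
            eta += coefs.get(m, 0.0) * x.get(m, 0.0)
        return eta

    def probability(self, outcome: str, x: Mapping[str, float], year: float) -> float:
        eta = self.linear_predictor(outcome, x, year)
        if self.scale == "logit":
            return float(expit(eta))
        return float(np.clip(eta, 0.0, 1.0))

    def stratum_probability(self, outcome: str, key: StratumKey, year: float = YEAR_REF) -> float:
        x = {
            "age_45_65": 1.0 if key.age_band == "45-65" else 0.0,
            "male": 1.0 if key.sex == "male" else 0.0,
            "urban": 1.0 if key.location == "urban" else 0.0,
            "income_mid": 1.0 if key.income == "mid" else 0.0,
            "income_high": 1.0 if key.income == "high" else 0.0,
        }
        return self.probability(outcome, x, year)


def _default_correlation() -> np.ndarray:
    names = list(CONTINUOUS_FACTORS)
    c = np.eye(len(names))
    pairs = {
        ("systolic_bp", "diastolic_bp"): 0.70,
        ("bmi", "waist"): 0.80,
        ("random_glucose_true", "fasting_glucose_true"): 0.70,
        ("fasting_glucose_true", "hba1c"): 0.60,
        ("random_glucose_true", "hba1c"): 0.50,
        ("bmi", "systolic_bp"): 0.25,
        ("waist", "systolic_bp"): 0.25,
        ("bmi", "diastolic_bp"): 0.20,
        ("waist", "diastolic_bp"): 0.20,
        ("bmi", "random_glucose_true"): 0.15,
        ("waist", "random_glucose_true"): 0.15,
        ("bmi", "fasting_glucose_true"): 0.15,
        ("waist", "fasting_glucose_true"): 0.15,
        ("bmi", "hba1c"): 0.10,
        ("waist", "hba1c"): 0.10,
        ("systolic_bp", "random_glucose_true"): 0.10,
        ("systolic_bp", "fasting_glucose_true"): 0.10,
        ("diastolic_bp", "random_glucose_true"): 0.05,
        ("diastolic_bp", "fasting_glucose_true"): 0.05,
        ("systolic_bp", "hba1c"): 0.10,
        ("diastolic_bp", "hba1c"): 0.05,
        ("ldl", "bmi"): 0.15,
        ("ldl", "waist"): 0.15,
        ("ldl", "systolic_bp"): 0.10,
        ("ldl", "diastolic_bp"): 0.05,
        ("ldl", "random_glucose_true"): 0.05,
        ("ldl", "fasting_glucose_true"): 0.05,
        ("ldl", "hba1c"): 0.05,
    }
    for (a, b), r in pairs.items():
        i, j = names.index(a), names.index(b)
        c[i, j] = c[j, i] = r
    return c


def default_risk_factor_params() -> RiskFactorParams:
    """Documented default biomarker distributions for Indian adults 25-65.

    Diabetic (undiagnosed) means sit above non-diabetic means for every
    glycaemic marker, so diabetic glucose stochastically dominates, which the
    glucometer and confirmatory screens rely on.
    """
    means = {
        "nondiabetic": {
            "systolic_bp": 122.0, "diastolic_bp": 78.0, "bmi": 23.0, "waist": 82.0,
            "random_glucose_true": 5.3, "fasting_glucose_true": 4.9,
            "hba1c": 5.5, "ldl": 2.9,
        },
        "diabetic": {
            "systolic_bp": 132.0, "diastolic_bp": 82.0, "bmi": 25.5, "waist": 90.0,
            "random_glucose_true": 8.2, "fasting_glucose_true": 8.8,
            "hba1c": 7.8, "ldl": 3.1,
        },
    }
    sds = {
        "nondiabetic": {
            "systolic_bp": 14.0, "diastolic_bp": 9.0, "bmi": 3.8, "waist": 10.0,
            "random_glucose_true": 0.13, "fasting_glucose_true": 0.10,
            "hba1c": 0.06, "ldl": 0.8,
        },
        "diabetic": {
            "systolic_bp": 16.0, "diastolic_bp": 10.0, "bmi": 4.2, "waist": 11.0,
            "random_glucose_true": 0.35, "fasting_glucose_true": 0.25,
            "hba1c": 0.15, "ldl": 0.9,
        },
    }
    return RiskFactorParams(
        means=means,
        sds=sds,
        correlation=_default_correlation(),
        family_history_probs={
            "nondiabetic": (0.80, 0.17, 0.03),
            "diabetic": (0.55, 0.35, 0.10),
        },
        physical_activity_probs={
            "nondiabetic": (0.25, 0.45, 0.30),
            "diabetic": (0.15, 0.40, 0.45),
        },
        smoker_prob={"nondiabetic": 0.15, "diabetic": 0.18},
    )


def default_ground_truth() -> GroundTruth:
    """Default truth on the logit scale.

    Intercepts refer to the reference stratum (age 25-44, female, rural, low
    income); moderator effects reproduce the qualitative national pattern:
    diabetes prevalence higher urban and at older ages, probability of being
    undiagnosed higher among women, rural residents and the poor.
    """
    coefficients = {
        "prevalence_total": {
            "intercept": logit(0.0426), "age_45_65": 0.90, "male": 0.05,
            "urban": 0.92, "income_mid": 0.25, "income_high": 0.50,
            "year": 0.02,
        },
        "undiagnosed_given_diabetes": {
            "intercept": logit(0.9168), "age_45_65": -0.35, "male": -0.65,
            "urban": -0.75, "income_mid": -0.35, "income_high": -0.65,
            "year": -0.01,
        },
        "hypertension": {
            "intercept": logit(0.17), "age_45_65": 0.80, "male": 0.15,
            "urban": 0.35, "income_mid": 0.10, "income_high": 0.20,
            "year": 0.01,
        },
        "obesity": {
            "intercept": logit(0.035), "age_45_65": 0.30, "male": -0.20,
            "urban": 0.80, "income_mid": 0.25, "income_high": 0.55,
            "year": 0.02,
        },
    }
    return GroundTruth(
        coefficients=coefficients,
        scale="logit",
        risk_factors=default_risk_factor_params(),
    )


@dataclass
class CohortStudyRecord:
    """Summary row for one published cohort study."""

    study_id: str
    year: int
    n: int
    shares: Mapping[str, float]  # all SHARE_COLUMNS
    proportions: Mapping[str, float]  # outcome -> observed proportion
    variances: Mapping[str, float]  # outcome -> sampling variance p(1-p)/n

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("study n must be >= 1")
        for family, cols in _SHARE_FAMILIES.items():
            s = sum(self.shares[c] for c in cols)
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"{self.study_id}: {family} shares sum to {s}")
        for outcome, v in self.variances.items():
            if v <= 0:
                raise ValueError(f"{self.study_id}: variance for {outcome} must be > 0")

    def moderator_values(self) -> dict[str, float]:
        return {m: float(self.shares[m]) for m in MODERATORS}


def simulate_cohort_studies(
    truth: GroundTruth,
    n_studies: int,
    seed: int | np.random.SeedSequence,
    *,
    between_study_sd: float | None = None,
    median_n: float = 5000.0,
    n_log_sd: float = 0.8,
    year_range: tuple[int, int] = (1990, 2014),
    outcomes: Sequence[str] = OUTCOMES,
    dirichlet_concentration: float = 4.0,
) -> list[CohortStudyRecord]:
    """Simulate a table of cohort-study summaries from known truth.

    Each study's true outcome proportion is the truth linear predictor at the
    study's moderator shares plus a Normal(0, between_study_sd) between-study
    effect on the model scale; the observed proportion adds Binomial(n)
    sampling noise.  ``between_study_sd`` defaults per scale (0.25 on the
    log-odds, 0.03 on raw proportions); 0 with very large ``median_n``
    recovers the noise-free limit.
    """
    if n_studies < 2:
        raise ValueError("need at least 2 studies")
    if between_study_sd is None:
        # heterogeneity on the model's own scale: SD 0.25 on the log-odds,
        # 0.03 on raw proportions
        between_study_sd = 0.25 if truth.scale == "logit" else 0.03
    rng = np.random.default_rng(seed)
    records: list[CohortStudyRecord] = []
    for j in range(n_studies):
        shares: dict[str, float] = {}
        for family, cols in _SHARE_FAMILIES.items():
            alpha = np.array(
                [DEFAULT_MARGINALS[_FAMILY_KEY[family]][_LEVEL_OF[c]] for c in cols]
            )
            draw = rng.dirichlet(dirichlet_concentration * len(cols) * alpha)
            for c, v in zip(cols, draw):
                shares[c] = float(v)
        year = int(rng.integers(year_range[0], year_range[1] + 1))
        if n_log_sd > 0:
            n = max(int(np.exp(np.log(median_n) + n_log_sd * rng.standard_normal())), 50)
        else:
            n = int(median_n)
        x = {m: shares[m] for m in MODERATORS}
        proportions: dict[str, float] = {}
        variances: dict[str, float] = {}
        for outcome in outcomes:
            eta = truth.linear_predictor(outcome, x, year)
            eta += between_study_sd * rng.standard_normal()
            if truth.scale == "logit":
                p_true = float(expit(eta))
            else:
                p_true = float(eta)
                if p_true < 0.0 or p_true > 1.0:
                    logger.warning(
                        "study %d outcome %s: true proportion %.4f clamped to [0,1]",
                        j, outcome, p_true,
                    )
                    p_true = float(np.clip(p_true, 0.0, 1.0))
            count = rng.binomial(n, p_true)
            # continuity guard keeps the proportion off 0/1 so logit transforms
            # and the p(1-p)/n variance stay finite
            p_hat = (count + 0.5) / (n + 1.0)
            proportions[outcome] = p_hat
            variances[outcome] = p_hat * (1.0 - p_hat) / n
        records.append(
            CohortStudyRecord(
                study_id=f"study_{j:03d}", year=year, n=n,
                shares=shares, proportions=proportions, variances=variances,
            )
        )
    return records


_FAMILY_KEY = {"age": "age_band", "sex": "sex", "location": "location", "income": "income"}
_LEVEL_OF = {
    "age_25_44": "25-44", "age_45_65": "45-65",
    "female": "female", "male": "male",
    "rural": "rural", "urban": "urban",
    "income_low": "low", "income_mid": "mid", "income_high": "high",
}


def studies_to_frame(records: Sequence[CohortStudyRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row: dict[str, object] = {"study_id": r.study_id, "year": r.year, "n": r.n}
        row.update({c: r.shares[c] for c in SHARE_COLUMNS})
        for outcome in r.proportions:
            row[f"p_{outcome}"] = r.proportions[outcome]
            row[f"v_{outcome}"] = r.variances[outcome]
        rows.append(row)
    return pd.DataFrame(rows)


def studies_from_frame(df: pd.DataFrame) -> list[CohortStudyRecord]:
    outcomes = [c[2:] for c in df.columns if c.startswith("p_")]
    records = []
    for row in df.itertuples():
        d = row._asdict()
        records.append(
            CohortStudyRecord(
                study_id=str(d["study_id"]), year=int(d["year"]), n=int(d["n"]),
                shares={c: float(d[c]) for c in SHARE_COLUMNS},
                proportions={o: float(d[f"p_{o}"]) for o in outcomes},
                variances={o: float(d[f"v_{o}"]) for o in outcomes},
            )
        )
    return records


# ---------------------------------------------------------------------------
# Unit costs

#: Placeholder per-person unit costs, 2014 US dollars.  These are documented
#: stand-ins (not WHO-CHOICE values) chosen so the confirmatory laboratory
#: test dominates, which reproduces the qualitative cost ordering of the four
#: strategies (glucometer cheapest overall despite the dearer first stage).
DEFAULT_UNIT_COSTS = {
    "questionnaire": 0.05,
    "glucometer": 0.15,
    "confirmatory_lab": 1.75,
    "overhead_per_person_year": 0.02,
}


@dataclass(frozen=True)
class UnitCosts:
    questionnaire: float
    glucometer: float
    confirmatory_lab: float
    overhead_per_person_year: float

    def __post_init__(self) -> None:
        for name, v in self.as_dict().items():
            if v < 0:
                raise ValueError(f"unit cost {name} must be >= 0, got {v}")

    def as_dict(self) -> dict[str, float]:
        return {
            "questionnaire": self.questionnaire,
            "glucometer": self.glucometer,
            "confirmatory_lab": self.confirmatory_lab,
            "overhead_per_person_year": self.overhead_per_person_year,
        }


def make_unit_costs(overrides: Mapping[str, float] | None = None) -> UnitCosts:
    """Unit-cost inputs; defaults are documented placeholders."""
    values = dict(DEFAULT_UNIT_COSTS)
    for key, v in (overrides or {}).items():
        if key not in values:
            raise ValueError(f"unknown cost activity {key!r}")
        values[key] = float(v)
    return UnitCosts(**values)
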