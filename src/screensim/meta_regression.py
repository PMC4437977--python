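"""Inverse-variance weighted mixed-effects meta-regression.

Study-level outcomes y_j are regressed on moderator shares (age, sex,
location, income composition of each study) plus calendar year:

    y_j = b0 + b1 x_1j + ... + bn x_nj + by year_j + u_j + e_j

with u_j ~ N(0, tau2) the between-study effect and e_j ~ N(0, v_j) the known
sampling error.  tau2 is estimated by restricted maximum likelihood; the
coefficients by generalised least squares with weights 1/(v_j + tau2).

The default working scale is the logit: observed proportions are transformed
with delta-method variances v_logit = v / (p(1-p))^2, which keeps every
back-transformed prediction inside [0,1].  A raw proportion scale is offered
for fidelity to the printed model; its predictions are clamped (and the
clamping logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg
from scipy.optimize import minimize_scalar
from scipy.special import expit, logit

from .strata import StratumKey, all_strata
from .synthetic_inputs import MODERATORS, YEAR_REF, CohortStudyRecord

logger = logging.getLogger(__name__)

#: Design columns, in order: intercept, moderators, centred year.
DESIGN_COLUMNS = ("intercept",) + MODERATORS + ("year",)


@dataclass
class MetaRegressionFit:
    """Fitted coefficients and uncertainty of one outcome's meta-regression."""

    outcome: str
    scale: str
    beta: np.ndarray  # aligned with columns
    vcov: np.ndarray
    tau2: float
    columns: tuple[str, ...] = DESIGN_COLUMNS
    year_ref: int = YEAR_REF
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))
    n_studies: int = 0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.vcov = np.asarray(self.vcov, dtype=float)
        p = len(self.columns)
        if self.beta.shape != (p,):
            raise ValueError("beta length must match design columns")
        if self.vcov.shape != (p, p):
            raise ValueError("vcov must be square, matching beta")
        if not np.allclose(self.vcov, self.vcov.T, atol=1e-10):
            raise ValueError("vcov must be symmetric")
        if np.linalg.eigvalsh(self.vcov).min() < -1e-8:
            raise ValueError("vcov must be positive semi-definite")
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")

    def coef(self, name: str) -> float:
        return float(self.beta[self.columns.index(name)])

    def se(self, name: str) -> float:
        i = self.columns.index(name)
        return float(np.sqrt(self.vcov[i, i]))


def _design_matrix(studies: Sequence[CohortStudyRecord], year_ref: int) -> np.ndarray:
    rows = []
    for s in studies:
        x = s.moderator_values()
        rows.append([1.0] + [x[m] for m in MODERATORS] + [s.year - year_ref])
    return np.asarray(rows, dtype=float)


def _check_collinearity(X: np.ndarray, columns: Sequence[str]) -> None:
    # QR with column pivoting exposes (near-)dependent columns by tiny |R_ii|
    _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps * 1e3
    bad = [columns[piv[i]] for i in range(len(diag)) if diag[i] < tol]
    if bad:
        raise ValueError(f"singular moderator design; collinear columns: {bad}")


def _reml_neg_loglik(tau2: float, y: np.ndarray, v: np.ndarray, X: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    xtwx = X.T @ (w[:, None] * X)
    beta = np.linalg.solve(xtwx, X.T @ (w * y))
    r = y - X @ beta
    sign, logdet = np.linalg.slogdet(xtwx)
    return 0.5 * (np.sum(np.log(v + tau2)) + logdet + np.sum(w * r * r))


def fit_meta_regression(
    studies: Sequence[CohortStudyRecord],
    outcome: str,
    scale: str = "logit",
    *,
    intercept_only: bool = False,
    tau2: float | None = None,
) -> MetaRegressionFit:
    """Fit the weighted mixed-effects meta-regression for one outcome.

    Parameters
    ----------
    studies
        Cohort summary rows carrying proportions and sampling variances.
    outcome
        Which recorded outcome to model.
    scale
        ``"logit"`` (default; delta-method variances) or ``"linear"``.
    intercept_only
        Drop all moderators and the year term (pooled mean model).
    tau2
        Fix the between-study variance instead of estimating it by REML
        (``tau2=0`` is the fixed-effect / inverse-variance pooled limit).
    """
    if scale not in ("logit", "linear"):
        raise ValueError("scale must be 'logit' or 'linear'")
    studies = list(studies)
    columns: tuple[str, ...] = ("intercept",) if intercept_only else DESIGN_COLUMNS
    p = len(columns)
    if tau2 is None and len(studies) < p + 1 and len(studies) != 1:
        raise ValueError(
            f"need at least {p + 1} studies to estimate {p} coefficients "
            f"plus between-study variance; got {len(studies)}"
        )
    if len(studies) < p:
        raise ValueError(f"need at least {p} studies for {p} coefficients")

    y = np.array([s.proportions[outcome] for s in studies], dtype=float)
    v = np.array([s.variances[outcome] for s in studies], dtype=float)
    if np.any(v <= 0):
        raise ValueError("all sampling variances must be > 0")
    if scale == "logit":
        eps = 1e-6
        pclip = np.clip(y, eps, 1 - eps)
        v = v / (pclip * (1.0 - pclip)) ** 2  # delta method
        y = logit(pclip)

    if intercept_only:
        X = np.ones((len(studies), 1))
    else:
        X = _design_matrix(studies, YEAR_REF)
    _check_collinearity(X, columns)

    if tau2 is not None:
        tau2_hat = float(tau2)
        if tau2_hat < 0:
            raise ValueError("tau2 must be >= 0")
    elif len(studies) == 1:
        tau2_hat = 0.0
    else:
        # profiled REML over tau2; bracket by the scale of observed dispersion
        upper = max(float(np.var(y)) * 10.0, float(np.max(v)) * 10.0, 1e-8)
        res = minimize_scalar(
            _reml_neg_loglik,
            bounds=(0.0, upper),
            args=(y, v, X),
            method="bounded",
            options={"xatol": 1e-10},
        )
        tau2_hat = max(float(res.x), 0.0)
        if _reml_neg_loglik(0.0, y, v, X) <= res.fun:
            tau2_hat = 0.0

    w = 1.0 / (v + tau2_hat)
    xtwx = X.T @ (w[:, None] * X)
    vcov = np.linalg.inv(xtwx)
    beta = vcov @ (X.T @ (w * y))
    vcov = (vcov + vcov.T) / 2.0
    return MetaRegressionFit(
        outcome=outcome,
        scale=scale,
        beta=beta,
        vcov=vcov,
        tau2=tau2_hat,
        columns=columns,
        residuals=y - X @ beta,
        n_studies=len(studies),
    )


# ---------------------------------------------------------------------------
# Prediction surfaces


class PrevalenceSurface:
    """Per-stratum probabilities for every modelled outcome."""

    def __init__(self, values: Mapping[str, Mapping[StratumKey, float]]):
        for outcome, per_stratum in values.items():
            for k in all_strata():
                if k not in per_stratum:
                    raise ValueError(f"{outcome}: missing stratum {k}")
                pv = per_stratum[k]
                if not (0.0 <= pv <= 1.0):
                    raise ValueError(f"{outcome}: probability {pv} outside [0,1]")
        self.values = {o: dict(m) for o, m in values.items()}

    def probability(self, outcome: str, key: StratumKey) -> float:
        return self.values[outcome][key]

    def outcomes(self) -> tuple[str, ...]:
        return tuple(self.values)

    def to_frame(self) -> "pd.DataFrame":
        import pandas as pd

        rows = []
        for k in all_strata():
            row = {
                "age_band": k.age_band, "sex": k.sex,
                "location": k.location, "income": k.income,
            }
            row.update({o: self.values[o][k] for o in self.values})
            rows.append(row)
        return pd.DataFrame(rows)


def _stratum_design(key: StratumKey, year: float, columns: Sequence[str], year_ref: int) -> np.ndarray:
    values = {
        "intercept": 1.0,
        "age_45_65": 1.0 if key.age_band == "45-65" else 0.0,
        "male": 1.0 if key.sex == "male" else 0.0,
        "urban": 1.0 if key.location == "urban" else 0.0,
        "income_mid": 1.0 if key.income == "mid" else 0.0,
        "income_high": 1.0 if key.income == "high" else 0.0,
        "year": year - year_ref,
    }
    return np.array([values[c] for c in columns])


def _surface_from_betas(
    fits: Mapping[str, MetaRegressionFit],
    betas: Mapping[str, np.ndarray],
    year: float,
) -> PrevalenceSurface:
    values: dict[str, dict[StratumKey, float]] = {}
    for outcome, fit in fits.items():
        beta = betas[outcome]
        per: dict[StratumKey, float] = {}
        for k in all_strata():
            eta = float(_stratum_design(k, year, fit.columns, fit.year_ref) @ beta)
            if fit.scale == "logit":
                per[k] = float(expit(eta))
            else:
                if eta < 0.0 or eta > 1.0:
                    logger.warning(
                        "%s prediction %.4f for %s clamped to [0,1]", outcome, eta, k
                    )
                per[k] = float(np.clip(eta, 0.0, 1.0))
        values[outcome] = per
    return PrevalenceSurface(values)


def predict_surface(
    fits: Mapping[str, MetaRegressionFit], year: float = YEAR_REF
) -> PrevalenceSurface:
    """Point predictions for all 24 strata at the given calendar year."""
    if not fits:
        raise ValueError("no fitted outcomes supplied")
    return _surface_from_betas(fits, {o: f.beta for o, f in fits.items()}, year)


def sample_surface(
    fits: Mapping[str, MetaRegressionFit],
    year: float,
    n_draws: int,
    seed: int | np.random.SeedSequence,
) -> list[PrevalenceSurface]:
    """Monte Carlo surfaces from the coefficient sampling distributions.

    Coefficient vectors are drawn from N(beta, vcov) independently per
    outcome; each draw maps to a full per-stratum surface.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    draws_by_outcome: dict[str, np.ndarray] = {}
    for outcome, fit in fits.items():
        eigmin = float(np.linalg.eigvalsh(fit.vcov).min())
        if eigmin < -1e-8:
            raise ValueError(f"{outcome}: vcov is not positive semi-definite")
        draws_by_outcome[outcome] = rng.multivariate_normal(
            fit.beta, fit.vcov, size=n_draws, method="eigh"
        )
    return [
        _surface_from_betas(
            fits, {o: draws_by_outcome[o][i] for o in fits}, year
        )
        for i in range(n_draws)
    ]
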