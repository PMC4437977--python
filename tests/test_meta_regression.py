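import json
import subprocess

import numpy as np
import pytest

from screensim import (
    default_ground_truth,
    fit_meta_regression,
    predict_surface,
    sample_surface,
    simulate_cohort_studies,
)
from screensim.meta_regression import DESIGN_COLUMNS, MetaRegressionFit
from screensim.strata import all_strata
from screensim.synthetic_inputs import CohortStudyRecord, MODERATORS


def record(y, v, shares=None, year=2015, study_id="s", n=1000):
    base = {
        "age_25_44": 0.5, "age_45_65": 0.5, "female": 0.5, "male": 0.5,
        "rural": 0.5, "urban": 0.5,
        "income_low": 1 / 3, "income_mid": 1 / 3, "income_high": 1 / 3,
    }
    base.update(shares or {})
    return CohortStudyRecord(
        study_id=study_id, year=year, n=n, shares=base,
        proportions={"prevalence_total": y}, variances={"prevalence_total": v},
    )


def test_two_equal_variance_studies_pool_to_mean():
    studies = [record(0.2, 0.01, study_id="a"), record(0.4, 0.01, study_id="b")]
    fit = fit_meta_regression(studies, "prevalence_total", scale="linear",
                              intercept_only=True)
    assert fit.coef("intercept") == pytest.approx(0.3, abs=1e-12)


def test_single_study_returns_its_estimate_with_zero_tau2():
    fit = fit_meta_regression(
        [record(0.27, 0.02)], "prevalence_total", scale="linear",
        intercept_only=True,
    )
    assert fit.coef("intercept") == pytest.approx(0.27, abs=1e-12)
    assert fit.tau2 == 0.0


def test_duplicating_a_precise_study_pulls_pooled_estimate_toward_it():
    lo_precision = [record(0.2, 0.02, study_id="a"), record(0.4, 0.02, study_id="b")]
    fit0 = fit_meta_regression(lo_precision, "prevalence_total", scale="linear",
                               intercept_only=True, tau2=0.0)
    extra = lo_precision + [record(0.4, 0.01, study_id="b2")]
    fit1 = fit_meta_regression(extra, "prevalence_total", scale="linear",
                               intercept_only=True, tau2=0.0)
    assert fit1.coef("intercept") > fit0.coef("intercept")


def test_fixed_effect_limit_matches_weighted_least_squares_oracle():
    """With tau2 pinned at 0 the fit must equal brute-force WLS."""
    rng = np.random.default_rng(5)
    studies = []
    for i in range(30):
        age = rng.uniform(0.2, 0.8)
        male = rng.uniform(0.3, 0.7)
        urb = rng.uniform(0.1, 0.9)
        mid = rng.uniform(0.1, 0.5)
        high = rng.uniform(0.1, 0.4)
        studies.append(
            record(
                float(rng.uniform(0.05, 0.4)), float(rng.uniform(0.001, 0.01)),
                shares={
                    "age_45_65": age, "age_25_44": 1 - age,
                    "male": male, "female": 1 - male,
                    "urban": urb, "rural": 1 - urb,
                    "income_mid": mid, "income_high": high,
                    "income_low": 1 - mid - high,
                },
                year=int(rng.integers(1995, 2015)), study_id=f"s{i}",
            )
        )
    fit = fit_meta_regression(studies, "prevalence_total", scale="linear", tau2=0.0)

    X = np.array(
        [[1.0] + [s.moderator_values()[m] for m in MODERATORS] + [s.year - 2015]
         for s in studies]
    )
    y = np.array([s.proportions["prevalence_total"] for s in studies])
    w = 1.0 / np.array([s.variances["prevalence_total"] for s in studies])
    sw = np.sqrt(w)
    beta_oracle, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    np.testing.assert_allclose(fit.beta, beta_oracle, atol=1e-8)


def test_reml_fit_matches_metafor_oracle(tmp_path):
    """Coefficients and tau2 agree with R metafor's REML meta-regression."""
    truth = default_ground_truth()
    studies = simulate_cohort_studies(truth, 15, seed=21)
    fit = fit_meta_regression(studies, "prevalence_total", scale="linear")

    import pandas as pd

    rows = []
    for s in studies:
        row = {"y": s.proportions["prevalence_total"],
               "v": s.variances["prevalence_total"],
               "year_c": s.year - 2015}
        row.update(s.moderator_values())
        rows.append(row)
    csv = tmp_path / "studies.csv"
    pd.DataFrame(rows).to_csv(csv, index=False)
    script = tmp_path / "fit.R"
    script.write_text(
        "suppressMessages(library(metafor))\n"
        f"d <- read.csv('{csv}')\n"
        "res <- rma(yi=y, vi=v, mods=~age_45_65+male+urban+income_mid+"
        "income_high+year_c, method='REML', data=d,\n"
        "           control=list(tol=1e-10))\n"
        "cat(jsonlite::toJSON(list(beta=as.numeric(res$beta), tau2=res$tau2),"
        "digits=12))\n"
    )
    out = subprocess.run(
        ["Rscript", "--vanilla", str(script)], capture_output=True, text=True,
        check=True,
    )
    ref = json.loads(out.stdout)
    np.testing.assert_allclose(fit.beta, np.asarray(ref["beta"]), atol=2e-5)
    assert fit.tau2 == pytest.approx(float(np.atleast_1d(ref["tau2"])[0]), abs=2e-6)


@pytest.mark.parametrize("outcome", ["prevalence_total", "undiagnosed_given_diabetes"])
def test_coefficient_recovery_within_two_se_over_many_seeds(truth, outcome):
    """>=90% of recovered coefficients fall within 2 estimated SE of truth."""
    hits = total = 0
    for seed in range(20):
        studies = simulate_cohort_studies(truth, 60, seed=seed)
        fit = fit_meta_regression(studies, outcome)
        for c in fit.columns:
            key = "intercept" if c == "intercept" else c
            t = truth.coefficients[outcome].get(key, 0.0)
            hits += abs(fit.coef(c) - t) <= 2 * fit.se(c)
            total += 1
    assert hits / total >= 0.90


def test_recovery_error_shrinks_with_study_count_and_size(truth):
    """Bias of the urban coefficient falls as studies grow in number/size."""

    def mae(n_studies, median_n):
        errs = []
        for seed in range(8):
            studies = simulate_cohort_studies(
                truth, n_studies, seed=seed, median_n=median_n, n_log_sd=0.0,
                between_study_sd=0.1,
            )
            fit = fit_meta_regression(studies, "prevalence_total")
            errs.append(abs(fit.coef("urban") - truth.coefficients["prevalence_total"]["urban"]))
        return float(np.mean(errs))

    assert mae(200, 50_000) < mae(20, 1_000)


def test_collinear_design_rejected():
    # all studies share identical moderator shares -> moderators collinear
    studies = [record(0.2 + 0.01 * i, 0.01, study_id=f"s{i}", year=2015)
               for i in range(10)]
    with pytest.raises(ValueError, match="collinear"):
        fit_meta_regression(studies, "prevalence_total", scale="linear")


def test_too_few_studies_rejected(truth):
    studies = simulate_cohort_studies(truth, 5, seed=0)
    with pytest.raises(ValueError, match="studies"):
        fit_meta_regression(studies, "prevalence_total")


class TestPredictSurface:
    def _intercept_fit(self, value, columns=DESIGN_COLUMNS, scale="logit"):
        beta = np.zeros(len(columns))
        beta[0] = value
        return MetaRegressionFit(
            outcome="prevalence_total", scale=scale, beta=beta,
            vcov=np.zeros((len(columns), len(columns))), tau2=0.0,
            columns=columns,
        )

    def test_intercept_only_gives_flat_surface(self):
        from scipy.special import logit

        fit = self._intercept_fit(logit(0.12))
        surface = predict_surface({"prevalence_total": fit}, 2015)
        for k in all_strata():
            assert surface.probability("prevalence_total", k) == pytest.approx(0.12)

    def test_positive_urban_coefficient_orders_urban_above_rural(self, fits):
        surface = predict_surface(fits, 2015)
        for k in all_strata():
            if k.location == "rural":
                urban_twin = type(k)(k.age_band, k.sex, "urban", k.income)
                assert (
                    surface.probability("prevalence_total", urban_twin)
                    > surface.probability("prevalence_total", k)
                )

    def test_zero_year_coefficient_time_invariant(self):
        fit = self._intercept_fit(0.3)
        s1 = predict_surface({"prevalence_total": fit}, 2000)
        s2 = predict_surface({"prevalence_total": fit}, 2015)
        for k in all_strata():
            assert s1.probability("prevalence_total", k) == s2.probability(
                "prevalence_total", k
            )


class TestSampleSurface:
    def test_zero_vcov_draws_equal_point_prediction(self, fits):
        fit = fits["prevalence_total"]
        frozen = MetaRegressionFit(
            outcome=fit.outcome, scale=fit.scale, beta=fit.beta,
            vcov=np.zeros_like(fit.vcov), tau2=fit.tau2, columns=fit.columns,
        )
        point = predict_surface({"prevalence_total": frozen}, 2015)
        draws = sample_surface({"prevalence_total": frozen}, 2015, 5, seed=0)
        for d in draws:
            for k in all_strata():
                assert d.probability("prevalence_total", k) == pytest.approx(
                    point.probability("prevalence_total", k), abs=1e-12
                )

    def test_empirical_draw_sd_matches_coefficient_se(self):
        fit = MetaRegressionFit(
            outcome="prevalence_total", scale="linear",
            beta=np.array([0.3]), vcov=np.array([[0.0025]]), tau2=0.0,
            columns=("intercept",),
        )
        draws = sample_surface({"prevalence_total": fit}, 2015, 10_000, seed=1)
        k = all_strata()[0]
        values = np.array([d.probability("prevalence_total", k) for d in draws])
        # clamping at [0,1] never triggers: 0.3 +- 0.05 stays well inside
        assert values.std(ddof=1) == pytest.approx(0.05, rel=0.05)

    def test_same_seed_identical_draws(self, fits):
        a = sample_surface(fits, 2015, 3, seed=9)
        b = sample_surface(fits, 2015, 3, seed=9)
        for da, db in zip(a, b):
            for k in all_strata():
                assert da.probability("prevalence_total", k) == db.probability(
                    "prevalence_total", k
                )
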