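"""Shared fixtures: one moderately sized synthetic world per session."""

import numpy as np
import pytest

from screensim import (
    build_population,
    default_ground_truth,
    load_all_instruments,
    make_demographics,
    predict_surface,
    simulate_cohort_studies,
)
from screensim.pipeline import fit_all_outcomes
from screensim.population import RiskFactorProfile


@pytest.fixture(scope="session")
def truth():
    return default_ground_truth()


@pytest.fixture(scope="session")
def demo():
    return make_demographics(586.0)


@pytest.fixture(scope="session")
def fits(truth):
    studies = simulate_cohort_studies(truth, 60, seed=7)
    return fit_all_outcomes(studies)


@pytest.fixture(scope="session")
def surface(fits):
    return predict_surface(fits, 2015)


@pytest.fixture(scope="session")
def population(demo, surface, truth):
    return build_population(demo, surface, truth.risk_factors, 120_000, seed=11)


@pytest.fixture(scope="session")
def eligible(population):
    return population.eligible_subset()


@pytest.fixture(scope="session")
def instruments():
    return load_all_instruments()


def make_profile(**overrides) -> RiskFactorProfile:
    """A low-risk baseline person; override fields per test."""
    base = dict(
        age=30.0, systolic_bp=110.0, diastolic_bp=70.0, bmi=22.0, waist=70.0,
        family_history="none",
        physical_activity="regular_exercise_and_strenuous_work",
        random_glucose_true=5.0, fasting_glucose_true=4.8, hba1c=5.4,
        ldl=2.5, smoker=False, cvd_history=False,
    )
    base.update(overrides)
    return RiskFactorProfile(**base)
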