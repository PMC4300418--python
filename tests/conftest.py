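import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import copdjm as cj

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def final_pop() -> cj.PopulationParameters:
    """Published final-model parameter set (recovery IIV preset)."""
    return cj.final_model_population()


@pytest.fixture(scope="session")
def plain_pop() -> cj.PopulationParameters:
    """Final model without covariate effects (reference-subject typicals)."""
    return cj.final_model_population(covariates=False)


@pytest.fixture(scope="session")
def small_trial(final_pop):
    """One simulated 300-subject trial under the final model."""
    design = cj.reference_design(n_subjects=300, seed=11)
    return cj.simulate_trial(final_pop, design, cj.reference_distributions())


@pytest.fixture(scope="session")
def reference_covariates():
    """A subject at all reference categories and reference continuous values."""
    return cj.CovariateVector(
        age=65.0, sex="female", height=170.0, weight=75.0, bmi=26.0,
        severity="moderate", reversibility="no", pics="no", smoking="no",
    )


def make_indiv(**kw) -> cj.IndividualParameters:
    base = dict(kin_i=0.116, int_dis_i=1.16, slope_dis_i=-1e-4,
                emax_i=0.36, edk50_i=0.36 * 8.66, kde_i=1.0, etas={})
    base.update(kw)
    return cj.IndividualParameters(**base)


@pytest.fixture
def indiv_factory():
    return make_indiv


def constant_path(value: float):
    return lambda t: np.broadcast_to(value, np.shape(t)) if np.ndim(t) else value
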