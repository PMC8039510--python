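import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from popmm.em_engine import FitSettings, NonConvergenceWarning, em_fit
from popmm.minimal_model import InsulinForcing, MMParams
from popmm.population_model import (PopulationParams,
                                    reference_base_population)
from popmm.synthetic_cohort import CohortSpec, simulate_trial

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def base_params() -> MMParams:
    return MMParams(GEZI=0.02, SI=5e-5, p2=0.04, V=12.0)


@pytest.fixture(scope="session")
def constant_forcing() -> InsulinForcing:
    return InsulinForcing(np.array([0.0, 360.0]), np.array([40.0, 40.0]), 40.0)


@pytest.fixture(scope="session")
def biphasic_forcing() -> InsulinForcing:
    t = np.array([0., 2., 4., 6., 10., 20., 22., 25., 30., 40., 60., 90.,
                  120., 180.])
    c = np.array([40., 300., 250., 180., 120., 60., 800., 600., 400., 200.,
                  100., 60., 45., 40.])
    return InsulinForcing(t, c, 40.0)


@pytest.fixture(scope="session")
def small_trial():
    """12 virtual subjects from the published base model (shared)."""
    spec = CohortSpec(n_subjects=12, true_pop=reference_base_population(),
                      seed=7)
    return simulate_trial(spec)


@pytest.fixture(scope="session")
def degenerate_trial():
    """Near-noiseless cohort at the base-model typical values."""
    base = reference_base_population()
    tiny = PopulationParams(base.mu_logtheta, 1e-4 * np.eye(4), effects=(),
                            sigma_prop=1e-3)
    spec = CohortSpec(n_subjects=12, true_pop=tiny, basal_noise_cv=1e-4,
                      seed=5)
    return simulate_trial(spec)


@pytest.fixture(scope="session")
def degenerate_fit(degenerate_trial):
    """EM fit of the near-noiseless cohort (shared across tests)."""
    st = FitSettings(n_importance_samples=200, max_iterations=25, seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NonConvergenceWarning)
        return em_fit(degenerate_trial.subjects, settings=st)
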