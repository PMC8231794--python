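import numpy as np
import pytest

from meropk import FixedParams, fit_poppk
from meropk.synthetic_data import AssayNoiseModel, CohortSpec, gen_cohort, gen_decay_series


@pytest.fixture
def zero_noise():
    return AssayNoiseModel(cv_proportional=0.0, replicates=1)


@pytest.fixture
def fixed_params():
    return FixedParams()


@pytest.fixture
def saline_series_clean(zero_noise):
    """Noise-free 2% infusate decay at the in vitro sampling schedule."""
    return gen_decay_series(0.006, 20000.0, noise=zero_noise,
                            metabolite_yield=1.0, seed=0)


@pytest.fixture
def toy_cohort(fixed_params):
    """Three sparse patients for likelihood-oracle comparisons."""
    return gen_cohort(CohortSpec(n_patients=3, samples_per_patient=3, seed=7),
                      fixed_params)


@pytest.fixture(scope="session")
def cohort300():
    """300 patients simulated at the published population parameters."""
    return gen_cohort(CohortSpec(n_patients=300, seed=1), FixedParams())


@pytest.fixture(scope="session")
def fit300(cohort300):
    return fit_poppk(cohort300, FixedParams(), method="laplace", seed=2)
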