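import numpy as np
import pytest

import interanimal as ia


@pytest.fixture(scope="session")
def small_cohort():
    """Two animals sharing a latent signal, quick enough for unit tests."""
    recs, gt = ia.generate_cohort(n_animals=2, n_units=30, n_stimuli=80,
                                  n_trials=20, n_latent=10, noise_sd=1.0,
                                  seed=101)
    return recs, gt


@pytest.fixture(scope="session")
def noiseless_cohort():
    recs, gt = ia.generate_cohort(n_animals=2, n_units=15, n_stimuli=40,
                                  n_trials=6, n_latent=5, noise_sd=0.0,
                                  seed=202)
    return recs, gt


@pytest.fixture(scope="session")
def fast_plans():
    return (ia.SplitHalfPlan(n_bootstraps=10, seed=5),
            ia.StimulusSplitPlan(n_splits=5, seed=6))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
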