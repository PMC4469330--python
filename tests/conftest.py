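import numpy as np
import pytest
from hypothesis import settings

import carrierflux as cf

# property tests must be reproducible run-to-run
settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def matrix():
    return cf.build_matrix()


@pytest.fixture(scope="session")
def pred_params():
    """The a-priori parameter set: h = 0.04, K = 1129 µM, V = 92 µM/min."""
    return cf.prediction_params()


@pytest.fixture(scope="session")
def noise_free():
    return cf.NoiseModel(cv=0.0, floor=0.0, n_replicates=1)


@pytest.fixture(scope="session")
def noise_free_dataset(pred_params, matrix, noise_free):
    return cf.generate_dataset(pred_params, matrix, noise=noise_free)


@pytest.fixture(scope="session")
def mixed_refit(noise_free_dataset, matrix):
    """Three-parameter mixed refit of noise-free data from the prediction set."""
    return cf.fit(noise_free_dataset, matrix, cf.FitSpec(variant="mixed"))


@pytest.fixture(scope="session")
def discrimination_study(matrix):
    """20 seeded noisy replicates (truth h = 0.16, cv = 10%, n = 5), both
    variants fitted per replicate.  Shared by the discrimination-power and
    noisy-identifiability checks."""
    truth = cf.prediction_params(h=cf.FITTED_H)
    reports = []
    for seed in range(20):
        noise = cf.NoiseModel(cv=0.10, floor=0.3, n_replicates=5, seed=seed)
        ds = cf.generate_dataset(truth, matrix, noise=noise)
        reports.append(cf.discriminate(ds, matrix))
    return reports


@pytest.fixture(scope="session")
def long_horizon_timecourses(pred_params, matrix):
    """Prediction-set simulation of all conditions far past the overshoot."""
    times = np.concatenate([[0.0], np.geomspace(0.25, 5000.0, 120)])
    return cf.simulate_conditions(pred_params, matrix, times)
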