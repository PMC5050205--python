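import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mfa2s.fitting import FitOptions, FitProblem, fit_fluxes
from mfa2s.synthetic_data import (
    build_toy_yeast_network,
    generate_measurements,
    sample_ground_truth,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: single ground-truth seed shared by the expensive session fixtures
GT_SEED = 11


@pytest.fixture(scope="session")
def toy_wry2():
    return build_toy_yeast_network("WRY2")


@pytest.fixture(scope="session")
def ground_truth(toy_wry2):
    return sample_ground_truth(toy_wry2, seed=GT_SEED)


@pytest.fixture(scope="session")
def noiseless_measurements(ground_truth):
    return generate_measurements(ground_truth, noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def noiseless_problem(toy_wry2, noiseless_measurements, ground_truth):
    return FitProblem(toy_wry2, noiseless_measurements, ground_truth.feed)


@pytest.fixture(scope="session")
def noiseless_fit(toy_wry2, noiseless_measurements, ground_truth,
                  noiseless_problem):
    return fit_fluxes(
        toy_wry2,
        noiseless_measurements,
        ground_truth.feed,
        FitOptions(n_starts=4, seed=0),
        problem=noiseless_problem,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
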