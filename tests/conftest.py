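import numpy as np
import pytest

import cardiopd as cpd
from cardiopd.simulate import TrialDesign, TruthParameters, simulate_trial


@pytest.fixture(scope="session")
def truth() -> TruthParameters:
    return TruthParameters.published_estimates()


@pytest.fixture(scope="session")
def small_trial(truth):
    """A 30-subject synthetic trial shared by fast tests."""
    design = TrialDesign(n_subjects=30)
    return simulate_trial(design, truth, seed=101)


@pytest.fixture(scope="session")
def full_trial(truth):
    """A full 206-subject synthetic trial at the default design."""
    return simulate_trial(seed=202)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def troponin_truth_theta():
    return {"trp0": 4.7, "ke": 8.49e-3, "slope": 8.84e-3, "type_effect": 0.524}


@pytest.fixture()
def troponin_truth_omega():
    return cpd.OmegaMatrix.from_cv(("trp0", "slope"), [39.2, 57.7])


@pytest.fixture()
def troponin_truth_sigma():
    return cpd.SigmaParams(sd=0.301)


@pytest.fixture()
def lvef_truth_theta():
    return {"lvef0": 0.599, "t_half_rec": 67.9, "ec50": 2.18e5,
            "trpmax_exponent": -1.16}


@pytest.fixture()
def lvef_truth_omega():
    return cpd.OmegaMatrix.from_cv(("lvef0", "ec50"), [7.07, 82.9],
                                   correlations={("lvef0", "ec50"): 0.585})


@pytest.fixture()
def lvef_truth_sigma():
    return cpd.SigmaParams(sd=0.078)
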