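import numpy as np
import pytest

import o2kin as ok


@pytest.fixture(scope="session")
def clean_truth():
    return ok.KineticsGroundTruth(vo2_rest=300.0, vo2_ss=1300.0, tau=1.0,
                                  delay=0.0, noise_sd=0.0)


@pytest.fixture(scope="session")
def noisy_truth():
    return ok.KineticsGroundTruth(vo2_rest=300.0, vo2_ss=1300.0, tau=1.0,
                                  delay=0.0, noise_sd=50.0)


@pytest.fixture(scope="session")
def fixed_protocol():
    return ok.ProtocolSpec(rest_duration_min=4.0)


@pytest.fixture(scope="session")
def clean_series(clean_truth, fixed_protocol):
    return ok.simulate_breath_series(clean_truth, fixed_protocol, seed=11)


@pytest.fixture(scope="session")
def noisy_series(noisy_truth, fixed_protocol):
    return ok.simulate_breath_series(noisy_truth, fixed_protocol, seed=11)


@pytest.fixture(scope="session")
def noisy_fit(noisy_series):
    w = ok.window_average(noisy_series)
    return ok.fit_kinetics(w), w


def window_midpoints(n=18, width_s=20.0):
    """Window midpoints in minutes for an n-window six-minute walk."""
    return (np.arange(n) + 0.5) * width_s / 60.0
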