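import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import shoegait as sg
from shoegait.calibration import PostureSet, fit_calibration
from shoegait.simulate import NO_NOISE, SensorNoise, sample_postures

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def profiles():
    young, older = sg.default_profiles()
    return {"young": young, "older": older}


@pytest.fixture(scope="session")
def noiseless_session(profiles):
    """Young-profile session without any sensor imperfections, plus truth."""
    session, truth = sg.simulate_session(
        profiles["young"], 10, noise=NO_NOISE, rng_seed=11
    )
    return session, truth


@pytest.fixture(scope="session")
def noisy_session(profiles):
    """Young-profile session with default sensor noise, plus truth and a
    calibration model fitted from synthetic stationary postures."""
    noise = SensorNoise()
    session, truth = sg.simulate_session(profiles["young"], 10, noise=noise, rng_seed=5)
    model = fit_calibration(PostureSet(sample_postures(noise, 20, 55)))
    return session, truth, model


@pytest.fixture(scope="session")
def analyzed_noiseless(noiseless_session):
    session, truth = noiseless_session
    return sg.analyze_session(session), truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
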