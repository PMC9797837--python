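import numpy as np
import pytest

from emgrecal import (
    EMGSeries, GestureInstance, Session, SimConfig, SessionPerturbation,
    make_gesture_templates, synthesize_session,
)


@pytest.fixture(scope="session")
def small_sim_config() -> SimConfig:
    """Reduced generator settings for fast unit tests (3 gestures, 4 holds)."""
    return SimConfig(n_gestures=3, n_instances_per_gesture=4, hold_ms=700.0,
                     idle_gap_ms=400.0)


@pytest.fixture(scope="session")
def small_templates(small_sim_config):
    return make_gesture_templates(small_sim_config, seed=7)


@pytest.fixture(scope="session")
def clean_session(small_sim_config, small_templates) -> Session:
    """One noise-free session without any session perturbation."""
    pert = SessionPerturbation(noise_sd_mv=0.0)
    return synthesize_session(small_templates, pert, small_sim_config,
                              seed=11, session_id="clean00")


@pytest.fixture()
def tiny_session() -> Session:
    """Hand-built minimal valid session (no simulator involved)."""
    n = 400
    t = np.arange(n, dtype=float)
    rng = np.random.default_rng(0)
    emg = EMGSeries(timestamps=t, samples=rng.normal(size=(8, n)),
                    units="millivolts", nominal_rate=1000.0)
    kin = np.arange(5.0, 395.0, 14.0)
    anns = [
        GestureInstance("Tap", 1, 20.0, 160.0),
        GestureInstance("Grab", 1, 220.0, 380.0),
    ]
    return Session(session_id="tiny", day_index=0, emg=emg,
                   kinematic_times=kin, annotations=anns)
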