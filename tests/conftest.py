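import numpy as np
import pytest

from gaitwin.experiment import ExperimentConfig, run_experiment
from gaitwin.simulate import (SimulationConfig, draw_subject_profile,
                              simulate_trial)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_trial(seed=0, duration=20.0, speed=1.25, placement="hand",
               marker_noise=0.5, **cfg_kw):
    """Small synthetic trial for unit tests."""
    cfg = SimulationConfig(trial_duration=duration, marker_noise_mm=marker_noise,
                           **cfg_kw)
    r = np.random.default_rng(seed)
    profile = draw_subject_profile(r, cfg, f"S{seed:02d}")
    return simulate_trial(profile, speed, placement, cfg, r), cfg


@pytest.fixture(scope="session")
def default_run():
    """The full default pipeline run shared by the acceptance checks.

    10 subjects x 3 speeds x 3 placements, 90 s trials, subject-wise 80/20
    split, four conv+LSTM detectors. Takes a few minutes; computed once.
    """
    return run_experiment(ExperimentConfig(seed=1))
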