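import numpy as np
import pandas as pd
import pytest

from snakegaze.design import ScreenGeometry, build_stimulus_set, make_aoi_set, stimuli_frame
from snakegaze.simulate import scaled_config, simulate_study


@pytest.fixture(scope="session")
def screen():
    return ScreenGeometry()


@pytest.fixture(scope="session")
def aois(screen):
    return make_aoi_set(screen)


@pytest.fixture(scope="session")
def default_stimuli():
    return build_stimulus_set()


@pytest.fixture(scope="session")
def tiny_study():
    """A small complete simulated study: (config, participants, trials,
    samples, stimuli_df), shared across tests that only read it."""
    cfg = scaled_config(n_per_cell=3)
    participants, trials, samples = simulate_study(cfg, seed=11)
    stim_df = stimuli_frame(
        build_stimulus_set(cfg.catalogue, allow_nonstandard_counts=True)
    )
    return cfg, participants, trials, samples, stim_df


def make_stream(x, y, valid=None, rate=30.0, trial_id="t"):
    """Monocular stream DataFrame from coordinate lists."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if valid is None:
        valid = np.ones(len(x), bool)
    t = np.arange(len(x)) * (1000.0 / rate)
    return pd.DataFrame(
        {"trial_id": trial_id, "t_ms": t, "x": x, "y": y,
         "valid": np.asarray(valid, bool)}
    )
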