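import math

import numpy as np
import pytest

from mgpipe.io_formats import MovieStack, StimulusProtocol, Trial
from mgpipe.synthetic_data import LayerModel, SimulationConfig


@pytest.fixture
def small_config():
    """A quick planar configuration for unit tests."""
    return SimulationConfig(field_px=(64, 64), n_mg=8, n_puffs_per_odour=1,
                            rng_seed=0)


@pytest.fixture
def sparse_noiseless_config():
    """Widely spaced blobs, no noise: for exact-recovery checks."""
    return SimulationConfig(field_px=(160, 160), n_mg=10,
                            min_spacing_factor=5.0, n_puffs_per_odour=1,
                            photon_gain=0.0, read_noise_sd=0.0, rng_seed=3)


@pytest.fixture
def single_odour_layer():
    return LayerModel(layer="PN_BOUTON",
                      odour_log_mean={"Oct": math.log(50.0)},
                      odour_log_sd={"Oct": 0.3},
                      active_fraction={"Oct": 1.0})


def make_movie(data, pixel_size_um=0.5, frame_rate_hz=9.0, z_step_um=1.0):
    return MovieStack(data=np.asarray(data, dtype=np.float32),
                      pixel_size_um=pixel_size_um, frame_rate_hz=frame_rate_hz,
                      z_step_um=z_step_um)


def make_protocol(trials, baseline_frames=5):
    return StimulusProtocol(trials=tuple(Trial(*t) for t in trials),
                            baseline_frames=baseline_frames)
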