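import numpy as np
import pytest

from calmech import SimConfig, generate_ground_truth, render_movie


@pytest.fixture
def small_config():
    """A compact movie configuration used across detection tests: clearly
    supra-threshold transients, modest noise, no bleaching (the bleached
    pipelines build their own configs)."""
    return SimConfig(
        frame_count=600, frame_rate=30.0, height=64, width=64,
        n_cells=5, soma_radius=3, event_rate=0.3, tau_true=1.5,
        amp_true=0.12, baseline=1000.0, bleach_fraction=0.0,
        noise_sd=2.0, seed=7,
    )


@pytest.fixture
def small_movie(small_config):
    truth = generate_ground_truth(small_config)
    stack = render_movie(truth, small_config)
    return small_config, truth, stack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
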