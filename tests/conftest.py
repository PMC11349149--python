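import numpy as np
import pytest

from meacomm import make_layout, stage_config, simulate_network


@pytest.fixture
def grid8():
    return make_layout(8, 8, 200.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def day14_sim():
    """One mid-development recording shared by read-only tests."""
    cfg = stage_config("day14", duration_s=120.0, seed=11)
    layout = make_layout(cfg.n_rows, cfg.n_cols, cfg.pitch_um)
    sts, gt = simulate_network(cfg, layout)
    return cfg, layout, sts, gt
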