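import numpy as np
import pytest

from photomat import LayerMask, SimConfig, generate_truth, simulate_rlc_stack


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(shape=(24, 24), layer_rows=20, mats_per_site=2)


@pytest.fixture(scope="session")
def truth(small_cfg):
    return generate_truth(small_cfg, seed=42)


@pytest.fixture(scope="session")
def noiseless_stack(truth, small_cfg):
    return simulate_rlc_stack(truth, ladder=small_cfg.ladder, noise_sd=0.0,
                              seed=1, mat_id="m1", site_id="AD")


@pytest.fixture()
def full_mask(truth) -> LayerMask:
    return truth.layer


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
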