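"""Shared fixtures: small synthetic datasets and reduced-width model configs.

Everything is generated programmatically from seeded configurations; no
fixture data is stored on disk.
"""

import numpy as np
import pytest

from yieldreg2d import SimConfig, generate_field_years
from yieldreg2d.hyper3dnetreg import ModelConfig


@pytest.fixture(scope="session")
def tiny_sim_cfg():
    """Small 20x20, 3-year field for fast pipeline tests."""
    return SimConfig(height=20, width=20, noise_sd=2.0, seed=11)


@pytest.fixture(scope="session")
def tiny_fields(tiny_sim_cfg):
    return generate_field_years(tiny_sim_cfg)


@pytest.fixture(scope="session")
def noise_free_fields():
    """Deterministic yield response (noise_sd = 0) on a 20x20 field."""
    return generate_field_years(SimConfig(height=20, width=20, noise_sd=0.0,
                                          seed=3))


def small_model_cfg(N: int, n: int = 8, seed: int = 0) -> ModelConfig:
    """Reduced-width architecture for cheap functional tests; the layer
    graph (dense 3-D blocks, separable 2-D encoder, N-dependent head) is
    identical to the full model."""
    return ModelConfig(N=N, n=n, conv3d_filters=4,
                       sep_channels=(16, 12, 10, 8, 6), seed=seed)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
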