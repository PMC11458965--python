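import numpy as np
import pytest

from reefchange.synthetic import (
    BandParams,
    ForwardModelParams,
    SceneConfig,
    default_bottom_library,
    default_forward_params,
    simulate_scene_pair,
)


@pytest.fixture(scope="session")
def noiseless_params() -> ForwardModelParams:
    return default_forward_params(noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_pair(noiseless_params):
    """A noiseless two-epoch site with a programmed 25 % coral loss."""
    cfg = SceneConfig(rows=96, cols=112, change_fraction=0.25, seed=11)
    return cfg, simulate_scene_pair(cfg, noiseless_params, default_bottom_library())


@pytest.fixture(scope="session")
def noisy_pair():
    """Default (0.5 % noise) site with clouds, no programmed change."""
    cfg = SceneConfig(rows=96, cols=112, cloud_fraction=0.03, seed=5)
    return cfg, simulate_scene_pair(cfg)


@pytest.fixture(scope="session")
def simple_band() -> BandParams:
    return BandParams(deep_water_radiance=1.0, surface_constant=1.0, attenuation=0.1)
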