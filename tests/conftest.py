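import numpy as np
import pytest

from pfseg.gamma import GrayscaleImage
from pfseg.model import NetworkConfig, PFSNet
from pfseg.synthdata import PhantomConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_config():
    """Smallest practical network: 64x64 input, 1/16 width."""
    return NetworkConfig.scaled((64, 64), width_mult=0.0625, seed=0)


@pytest.fixture(scope="session")
def tiny_net(tiny_config):
    return PFSNet(tiny_config)


@pytest.fixture(scope="session")
def short_phantom():
    """A 60-frame noise-free phantom for fast deterministic checks."""
    from pfseg.synthdata import simulate_recovery

    cfg = PhantomConfig(seed=7, frames=60, noise_sd_c=0.0, nonuniform_cooling=False)
    return simulate_recovery(cfg)


def random_mask(rng, shape=(16, 16), p=0.3):
    return rng.uniform(size=shape) < p
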