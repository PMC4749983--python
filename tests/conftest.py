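import numpy as np
import pytest

import bulbsparse as bs


@pytest.fixture(scope="session")
def fixtures():
    return bs.generate_fixtures(seed=0)


@pytest.fixture(scope="session")
def small_panel():
    """8-odor panel over a 20-glomerulus tract (reduced-preset scale)."""
    return bs.generate_panel(20, 8, 15, seed=2)


@pytest.fixture(scope="session")
def tiny_config():
    """Very small network for fast dynamics tests."""
    return bs.NetworkConfig(n_glomeruli=8, tract_length=3.0)


@pytest.fixture()
def tiny_network(tiny_config):
    return bs.build_network(tiny_config, seed=3)


@pytest.fixture(scope="session")
def tiny_panel():
    return bs.generate_panel(8, 3, 6, seed=0)


@pytest.fixture()
def minimal_network():
    cfg = bs.NetworkConfig(
        n_glomeruli=1,
        mitral_per_glomerulus=1,
        granule_per_mitral=1,
        segments_per_dendrite=1,
        tract_length=1.5,
        contacts_per_granule=1.0,
    )
    return bs.build_network(cfg, seed=0)
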