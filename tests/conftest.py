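import numpy as np
import pytest

from xenosig.synthetic_data import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cfg():
    """Desk-scale study configuration for fast cross-module tests."""
    return SimConfig(
        seed=7,
        n_samples=120,
        n_genes=400,
        n_anchor_pos=40,
        n_anchor_neg=40,
        n_de=80,
        n_reads=1500,
        n_proteins=300,
        n_sets=5,
        set_size=20,
    )
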