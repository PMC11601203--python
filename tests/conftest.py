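import numpy as np
import pytest

from thermoplm.model import ModelConfig, ThermoPLM
from thermoplm.synthetic import DEFAULT_CONSENSUS


@pytest.fixture(scope="session")
def wild_type() -> str:
    return DEFAULT_CONSENSUS[:48]


@pytest.fixture(scope="session")
def tiny_model(wild_type) -> ThermoPLM:
    """One shared untrained desk-scale model (tests must not mutate it)."""
    return ThermoPLM(ModelConfig(n_layers=2, n_heads=4, embed_dim=32,
                                 max_len=128, seed=0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
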