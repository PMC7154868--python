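import numpy as np
import pytest

from rbpkit import synthetic

PLANTED = "UGGUUGGU"


@pytest.fixture(scope="session")
def planted_kmer() -> str:
    return PLANTED


@pytest.fixture(scope="session")
def planted_model() -> synthetic.BindingModel:
    """Single planted 8-mer at affinity 100 over background 1."""
    return synthetic.BindingModel({PLANTED: 100.0}, background_affinity=1.0)


@pytest.fixture(scope="session")
def small_config() -> synthetic.SelectionConfig:
    return synthetic.SelectionConfig(n_input_reads=5000, n_pulldown_reads=5000, seed=42)


@pytest.fixture(scope="session")
def small_input_pool(small_config) -> synthetic.ReadPool:
    return synthetic.generate_input_pool(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
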