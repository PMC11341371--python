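import numpy as np
import pytest

from epiattn import SynthSpec, Vocabulary, generate_epi_dataset
from epiattn.nn.model import EPIModel, ModelConfig


@pytest.fixture(scope="session")
def vocab() -> Vocabulary:
    return Vocabulary()


@pytest.fixture(scope="session")
def tiny_model(vocab) -> EPIModel:
    """A small randomly initialized model for contract checks."""
    cfg = ModelConfig.desk_scale(max_positions=128)
    return EPIModel(cfg, seed=0, vocab_hash=vocab.content_hash())


@pytest.fixture(scope="session")
def small_dataset():
    """A quick synthetic dataset with short elements for pipeline tests."""
    spec = SynthSpec(n_pos=30, n_neg=60, enh_len=120, prom_len=80,
                     mutation_rate=0.0, plant_prob=1.0, seed=7)
    return generate_epi_dataset(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
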