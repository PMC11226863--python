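import numpy as np
import pytest

from codonmlm import (
    Cds,
    CodonUsageTable,
    ModelConfig,
    SyntheticSpec,
    TrainConfig,
    TranscriptRecord,
    generate_synthetic_corpus,
)
from codonmlm.model import DualStreamEncoder
from codonmlm.training import CodonModel


@pytest.fixture(scope="session")
def uniform_table() -> CodonUsageTable:
    """Every codon counted once: all w = 1, modal codons are the
    lexicographic family heads."""
    return CodonUsageTable.from_counts({})


@pytest.fixture(scope="session")
def skewed_table() -> CodonUsageTable:
    """AAA twice as frequent as AAG, everything else uniform."""
    counts = {"AAA": 4.0, "AAG": 2.0}
    return CodonUsageTable.from_counts(counts)


@pytest.fixture(scope="session")
def small_corpus() -> list[TranscriptRecord]:
    return generate_synthetic_corpus(
        SyntheticSpec(n_sequences=20, length_range=(5, 12), seed=7)
    )


@pytest.fixture(scope="session")
def micro_config() -> ModelConfig:
    return ModelConfig(embed_dim=16, n_blocks=1, n_heads=2, ff_dim=32, max_len=16)


@pytest.fixture(scope="session")
def untrained_network(micro_config) -> DualStreamEncoder:
    return DualStreamEncoder(micro_config, seed=0)


@pytest.fixture(scope="session")
def overfit_results():
    """A micro model overfit on 10 deterministic-rule sequences; shared by
    decoding / evaluation tests that need a model that has actually
    learned something."""
    corpus = generate_synthetic_corpus(
        SyntheticSpec(n_sequences=10, length_range=(5, 8), deterministic_rule=True, seed=5)
    )
    cfg = ModelConfig(embed_dim=32, n_blocks=1, n_heads=2, ff_dim=64, max_len=16)
    tc = TrainConfig.compressed(epochs=60, seed=0)
    model = CodonModel(corpus, model_config=cfg, train_config=tc, seed=0)
    return model.fit()
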