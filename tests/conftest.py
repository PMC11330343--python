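import numpy as np
import pytest

from gdafusion.encoders import EncoderSpec, ToyEncoder
from gdafusion.records import (
    AssociationDataset,
    AssociationPair,
    DiseaseRecord,
    GeneRecord,
)
from gdafusion.synthetic import SyntheticConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dataset():
    """Four genes, four diseases, one positive pair per index-matched couple."""
    rng = np.random.default_rng(0)
    genes = {
        f"g{i}": GeneRecord(f"g{i}", "".join(rng.choice(list("ACDEFGHIK"), size=12)))
        for i in range(4)
    }
    diseases = {
        f"d{i}": DiseaseRecord(
            f"d{i}", f"disease {i}",
            " ".join(rng.choice(["alpha", "beta", "gamma", "delta", "omega"], size=6)),
        )
        for i in range(4)
    }
    pairs = [AssociationPair(f"g{i}", f"d{i}", 1) for i in range(4)]
    return AssociationDataset(genes=genes, diseases=diseases, pairs=pairs)


@pytest.fixture
def small_encoders():
    protein = ToyEncoder(EncoderSpec("protein", hidden_size=8, max_tokens=16))
    text = ToyEncoder(EncoderSpec("text", hidden_size=8, max_tokens=16))
    return protein, text


@pytest.fixture(scope="session")
def small_corpus():
    """A quick learnable corpus shared by slower integration tests."""
    cfg = SyntheticConfig(n_genes=40, n_diseases=40, n_clusters=2, seed=99)
    dataset, truth = generate(cfg)
    return dataset, truth, cfg
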