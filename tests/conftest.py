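import numpy as np
import pytest

from atacvar.gkm import GkmParams, TrainingSet, train
from atacvar.simulate import SyntheticDatasetSpec, make_dataset


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_dataset():
    """Small but complete synthetic universe shared across test modules."""
    spec = SyntheticDatasetSpec(
        seed=1,
        n_chroms=2,
        chrom_length=200_000,
        n_enhancers_popA=15,
        n_enhancers_popB=15,
        n_shared=15,
        n_background_snps=1500,
    )
    return make_dataset(spec)


@pytest.fixture(scope="session")
def tiny_model():
    """A quick model trained on short motif-planted sequences."""
    rng = np.random.default_rng(7)
    motif = "ACCGGAAGTG"
    pos = [
        random_dna(rng, 40) + motif + random_dna(rng, 50) for _ in range(40)
    ]
    neg = [random_dna(rng, 100) for _ in range(120)]
    ts = TrainingSet(pos, neg)
    return train(ts, GkmParams()), ts
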