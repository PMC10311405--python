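"""Shared fixtures: synthetic pore models, references, and a built index.

Everything is generated programmatically and deterministically; no data
files are read from disk.
"""

import numpy as np
import pytest

from squigseed.indexer import IndexParams, build_index
from squigseed.pore_model import PoreModel, all_kmers
from squigseed.signal_sim import synthetic_pore_model


def random_sequence(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def model_k6() -> PoreModel:
    return synthetic_pore_model(k=6, seed=20)


@pytest.fixture(scope="session")
def model_k3() -> PoreModel:
    """A tiny hand-checkable k=3 model with distinct integer levels."""
    levels = {kmer: float(10 + i) for i, kmer in enumerate(all_kmers(3))}
    return PoreModel(k=3, levels=levels)


@pytest.fixture(scope="session")
def reference_100k(model_k6):
    return [("chr1", random_sequence(100_000, seed=101))]


@pytest.fixture(scope="session")
def index_100k(reference_100k, model_k6):
    return build_index(reference_100k, model_k6, IndexParams())
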