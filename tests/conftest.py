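import numpy as np
import pytest

from glrfamevo.core_model import Alignment, Gene, GeneSet, SequenceRecord


@pytest.fixture
def simple_geneset() -> GeneSet:
    """Ten genes on two chromosomes with known ranks."""
    genes = [Gene(f"g{i}", "chr1", 1 + i * 1000, 500 + i * 1000) for i in range(6)]
    genes += [Gene(f"h{i}", "chr2", 1 + i * 1000, 500 + i * 1000) for i in range(4)]
    return GeneSet("test", genes)


@pytest.fixture
def identical_alignment() -> Alignment:
    return Alignment(["a", "b", "c"], ["MKVL", "MKVL", "MKVL"], "protein")


def random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, size=n))


@pytest.fixture
def rng7() -> np.random.Generator:
    return np.random.default_rng(7)
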