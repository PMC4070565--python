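import numpy as np
import pytest

from mitopart.seqdata import Alignment, GeneEntry, GeneMap
from mitopart.simulate import make_fixture_study, reference_gene_map


@pytest.fixture(scope="session")
def ref_gene_map() -> GeneMap:
    return reference_gene_map()


@pytest.fixture(scope="session")
def mini_bundle():
    """The reduced-scale simulated study dataset (fixed seed)."""
    return make_fixture_study("nymphalid-mini", seed=42)


@pytest.fixture
def toy_alignment() -> Alignment:
    return Alignment.from_sequences([
        ("s1", "ACGTAC"),
        ("s2", "ACGTAC"),
        ("s3", "ACTTAC"),
        ("s4", "ACTTTC"),
    ])


@pytest.fixture
def tiny_gene_map() -> GeneMap:
    """Two PCGs, one rRNA, two tRNAs over a 40-column toy matrix."""
    return GeneMap([
        GeneEntry("pcgA", 0, 12, "PCG", 0, "+"),
        GeneEntry("trnX", 12, 16, "tRNA", None, "+"),
        GeneEntry("pcgB", 16, 27, "PCG", 2, "-"),
        GeneEntry("rrnX", 27, 36, "rRNA", None, "+"),
        GeneEntry("trnY", 36, 40, "tRNA", None, "-"),
    ])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
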