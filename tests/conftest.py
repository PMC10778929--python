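import numpy as np
import pytest

from cubscape._codes import CODONS, SYN_FAMILIES
from cubscape.seqio import CodingSequence, CodonUsageTable
from cubscape.synthetic_data import generate_homolog_set, make_codon_table


@pytest.fixture(scope="session")
def uniform_table() -> CodonUsageTable:
    """All synonymous frequencies equal -> every weight is 1."""
    return CodonUsageTable("uniform", {c: 1000.0 / 64 for c in CODONS})


@pytest.fixture(scope="session")
def skewed_table() -> CodonUsageTable:
    """Reproducible random table with clear frequent/rare codons."""
    return make_codon_table("skewed", skew=2.0, seed=1234)


@pytest.fixture(scope="session")
def small_homolog_set():
    """Three unbiased 200-codon homologs with their usage tables."""
    return generate_homolog_set(200, 3, seed=20231227, gene="geneA")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20231227)


def most_frequent_cds(table: CodonUsageTable, protein: str) -> CodingSequence:
    """CDS encoding ``protein`` with each residue's highest-weight codon."""
    codons = []
    for aa in protein:
        fam = SYN_FAMILIES[aa]
        codons.append(max(fam, key=lambda c: table.weights.get(c, 0.0)))
    return CodingSequence(id="maxw", seq="".join(codons))
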