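"""Standard genetic code lookups shared across modules.

The canonical internal alphabet is DNA (A/C/G/T); the stop symbol is ``*``.
Everything here is derived once from Biopython's standard codon table.
"""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"

#: all 64 codons in lexicographic order (DNA alphabet)
CODONS: tuple[str, ...] = tuple(a + b + c for a in BASES for b in BASES for c in BASES)

STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)

#: codon -> one-letter amino acid, stops mapped to "*"
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
CODON_TO_AA.update({c: "*" for c in STOP_CODONS})

#: amino acid (or "*") -> tuple of synonymous codons, lexicographic order
SYN_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in CODONS:
    SYN_FAMILIES.setdefault(CODON_TO_AA[_codon], tuple())
SYN_FAMILIES = {
    aa: tuple(c for c in CODONS if CODON_TO_AA[c] == aa) for aa in SYN_FAMILIES
}

#: amino acid -> number of synonymous codons (degeneracy); "*" included
DEGENERACY: dict[str, int] = {aa: len(fam) for aa, fam in SYN_FAMILIES.items()}

#: the two amino acids with a single codon under the standard code
SINGLE_CODON_AAS: frozenset[str] = frozenset(
    aa for aa, k in DEGENERACY.items() if k == 1
)

SENSE_CODONS: tuple[str, ...] = tuple(c for c in CODONS if c not in STOP_CODONS)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a DNA codon; "*" for stops, "X" if ambiguous."""
    return CODON_TO_AA.get(codon, "X")


def gc_count(codon: str) -> int:
    return sum(1 for b in codon if b in "GC")
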