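"""Classification of coding single-nucleotide substitutions and the
synonymous/missense abundance summaries.

Classification compares the affected codon's translation before and after
the substitution under the standard genetic code: synonymous (same amino
acid, or stop -> stop), missense (sense -> different sense), nonsense
(sense -> stop) and stop_loss (stop -> sense).  Only single-nucleotide
substitutions are in scope.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

from ._codes import translate_codon
from .seqio import CodingSequence, VariantRecord

SYNONYMOUS = "synonymous"
MISSENSE = "missense"
NONSENSE = "nonsense"
STOP_LOSS = "stop_loss"


def classify_substitution(cds: CodingSequence, variant: VariantRecord) -> str:
    """Classify one substitution by its before/after codon translation."""
    pos = variant.cds_position
    if pos >= len(cds.seq):
        raise ValueError(
            f"variant position {pos} beyond CDS length {len(cds.seq)} of {cds.id!r}"
        )
    if cds.seq[pos] != variant.ref:
        raise ValueError(
            f"ref mismatch at CDS position {pos} of {cds.id!r}: "
            f"expected {variant.ref!r}, sequence has {cds.seq[pos]!r}"
        )
    codon_idx, offset = divmod(pos, 3)
    before = cds.codons[codon_idx]
    after = before[:offset] + variant.alt + before[offset + 1 :]
    aa_before = translate_codon(before)
    aa_after = translate_codon(after)
    if "X" in (aa_before, aa_after):
        raise ValueError(f"ambiguous codon at position {pos} of {cds.id!r}")
    if aa_before == aa_after:
        return SYNONYMOUS
    if aa_after == "*":
        return NONSENSE
    if aa_before == "*":
        return STOP_LOSS
    return MISSENSE


@dataclass
class MutationSummary:
    """Counts per substitution class with the two abundance percentages:
    synonymous relative to all mutations, and synonymous relative to
    missense mutations."""

    n_total: int
    n_synonymous: int
    n_missense: int
    n_nonsense: int
    n_stop_loss: int
    syn_vs_all_pct: float
    syn_vs_missense_pct: float  # NaN when there are no missense mutations

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_synonymous": self.n_synonymous,
            "n_missense": self.n_missense,
            "n_nonsense": self.n_nonsense,
            "n_stop_loss": self.n_stop_loss,
            "syn_vs_all_pct": self.syn_vs_all_pct,
            "syn_vs_missense_pct": self.syn_vs_missense_pct,
        }


def summarize_mutations(
    cds: CodingSequence, variants: Sequence[VariantRecord]
) -> MutationSummary:
    """Class counts and abundance percentages over a variant list."""
    if not variants:
        raise ValueError("empty variant list")
    counts = {SYNONYMOUS: 0, MISSENSE: 0, NONSENSE: 0, STOP_LOSS: 0}
    for v in variants:
        counts[classify_substitution(cds, v)] += 1
    n_total = len(variants)
    n_syn = counts[SYNONYMOUS]
    n_mis = counts[MISSENSE]
    if n_mis == 0:
        warnings.warn("no missense mutations: synonymous/missense ratio undefined")
        syn_vs_mis = math.nan
    else:
        syn_vs_mis = 100.0 * n_syn / n_mis
    return MutationSummary(
        n_total=n_total,
        n_synonymous=n_syn,
        n_missense=n_mis,
        n_nonsense=counts[NONSENSE],
        n_stop_loss=counts[STOP_LOSS],
        syn_vs_all_pct=100.0 * n_syn / n_total,
        syn_vs_missense_pct=syn_vs_mis,
    )
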