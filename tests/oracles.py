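"""Independent oracles used by the test suite.

Everything here is written from first principles (hand-typed genetic
code, explicit recursive enumeration of nested structures) and must stay
independent of the package implementation it checks.
"""

from __future__ import annotations

#: standard genetic code, hand-typed (DNA codons; '*' = stop)
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_PAIR_E = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "U"): -2.0, ("U", "A"): -2.0,
    ("G", "U"): -1.0, ("U", "G"): -1.0,
}


def min_energy_enumeration(seq: str) -> float:
    """Minimum energy over ALL nested secondary structures of ``seq``
    (pairs GC=-3/AU=-2/GU=-1, hairpin loop >= 3, no pseudoknots) by plain
    recursive enumeration, no memoization.  Exponential; use n <= 18."""
    s = seq.upper().replace("T", "U")

    def rec(i: int, j: int) -> float:
        if j - i < 4:
            return 0.0
        best = rec(i + 1, j)  # i unpaired
        for k in range(i + 4, j + 1):
            e = _PAIR_E.get((s[i], s[k]))
            if e is not None:
                best = min(best, e + rec(i + 1, k - 1) + rec(k + 1, j))
        return best

    return rec(0, len(s) - 1) if s else 0.0


def count_structures(seq: str) -> int:
    """Number of nested structures (same constraints), for sanity checks."""
    s = seq.upper().replace("T", "U")

    def rec(i: int, j: int) -> int:
        if j - i < 4:
            return 1
        total = rec(i + 1, j)
        for k in range(i + 4, j + 1):
            if (s[i], s[k]) in _PAIR_E:
                total += rec(i + 1, k - 1) * rec(k + 1, j)
        return total

    return rec(0, len(s) - 1) if s else 1


def wright_nc_single_two_fold(n1: int, n2: int) -> float | None:
    """Nc of a region containing a single two-fold family with counts
    (n1, n2), by direct evaluation of the estimator."""
    n = n1 + n2
    if n < 2:
        return None
    sum_p2 = (n1 / n) ** 2 + (n2 / n) ** 2
    f_hat = (n * sum_p2 - 1) / (n - 1)
    if f_hat <= 0:
        return None
    return 1.0 / f_hat
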