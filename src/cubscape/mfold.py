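"""Local mRNA folding-energy profiles (ΔLFE).

The quantity of interest is the difference, per sliding window, between
the minimum free energy (MFE) of the native coding sequence and the mean
MFE of the same window taken from whole-sequence synonymous-codon
permutations:

    ΔLFE(w) = LFE_native(w) - mean_p LFE_perm_p(w)

Negative ΔLFE means the native mRNA folds more strongly than expected
for its protein, codon multiset and nucleotide content; positive ΔLFE
means weaker-than-predicted structure.  Profiles use 40-nt windows at a
10-nt step, anchored at the window start, measured from the CDS start.

The default folding backend is a Nussinov-style nested-structure dynamic
program with stacking-free pair energies (GC = -3, AU = -2, GU = -1,
minimum hairpin loop of 3 unpaired bases).  Its absolute energies are in
arbitrary units; ΔLFE's sign and zero structure are the portable
quantities.  A ViennaRNA thermodynamic backend (kcal/mol) is pluggable
behind the same contract.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Protocol, Sequence

import numpy as np
from numba import njit

from ._codes import translate_codon
from .seqio import CodingSequence

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 40
DEFAULT_STEP = 10
DEFAULT_N_PERMUTATIONS = 20
MIN_HAIRPIN_LOOP = 3

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3, "N": 4}

# pair energies, indexed by base codes 0..3; 0 = not pairable
_PAIR_E = np.zeros((4, 4), dtype=np.float64)
_PAIR_E[2, 1] = _PAIR_E[1, 2] = -3.0  # G:C
_PAIR_E[0, 3] = _PAIR_E[3, 0] = -2.0  # A:U
_PAIR_E[2, 3] = _PAIR_E[3, 2] = -1.0  # G:U


def encode(seq: str) -> np.ndarray:
    """Encode an RNA/DNA string to base codes (A=0, C=1, G=2, U/T=3, N=4)."""
    try:
        return np.array([_BASE_INDEX[b] for b in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid base {exc} in sequence") from exc


@njit(cache=False)
def _fold_dp_nb(arr, pair_e):  # pragma: no cover - exercised via wrapper
    n = arr.shape[0]
    E = np.zeros((n, n), dtype=np.float64)
    for span in range(MIN_HAIRPIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = E[i, j - 1]  # j unpaired
            for k in range(i, j - MIN_HAIRPIN_LOOP):
                e = pair_e[arr[k], arr[j]]
                if e < 0.0:
                    left = E[i, k - 1] if k > i else 0.0
                    inner = E[k + 1, j - 1] if k + 1 <= j - 1 else 0.0
                    cand = left + e + inner
                    if cand < best:
                        best = cand
            E[i, j] = best
    return E[0, n - 1] if n > 0 else 0.0


@njit(cache=False)
def _fold_windows_nb(arr, starts, window, pair_e):  # pragma: no cover
    out = np.empty(starts.shape[0], dtype=np.float64)
    for w in range(starts.shape[0]):
        s = starts[w]
        sub = arr[s : s + window].copy()
        skip = False
        for b in sub:
            if b > 3:
                skip = True
                break
        out[w] = np.nan if skip else _fold_dp_nb(sub, pair_e)
    return out


def fold_dp_reference(seq: str) -> tuple[float, str]:
    """Pure-Python reference DP with traceback.

    Returns ``(energy, dot_bracket)``.  Used as an independently written
    cross-check of the accelerated path and for inspecting structures.
    """
    arr = encode(seq)
    if np.any(arr > 3):
        raise ValueError("reference fold does not accept N bases")
    n = len(arr)
    E = [[0.0] * n for _ in range(n)]
    for span in range(MIN_HAIRPIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = E[i][j - 1]
            for k in range(i, j - MIN_HAIRPIN_LOOP):
                e = _PAIR_E[arr[k], arr[j]]
                if e < 0:
                    left = E[i][k - 1] if k > i else 0.0
                    inner = E[k + 1][j - 1] if k + 1 <= j - 1 else 0.0
                    cand = left + e + inner
                    if cand < best:
                        best = cand
            E[i][j] = best

    structure = ["."] * n

    def trace(i: int, j: int) -> None:
        while j > i:
            if j - i <= MIN_HAIRPIN_LOOP:
                return
            if E[i][j] == E[i][j - 1]:
                j -= 1
                continue
            for k in range(i, j - MIN_HAIRPIN_LOOP):
                e = _PAIR_E[arr[k], arr[j]]
                if e < 0:
                    left = E[i][k - 1] if k > i else 0.0
                    inner = E[k + 1][j - 1] if k + 1 <= j - 1 else 0.0
                    if math.isclose(E[i][j], left + e + inner):
                        structure[k] = "("
                        structure[j] = ")"
                        trace(k + 1, j - 1)
                        j = k - 1
                        break
            else:  # numerical safety; should not happen
                j -= 1

    if n > 0:
        trace(0, n - 1)
    return E[0][n - 1] if n else 0.0, "".join(structure)


class FoldingBackend(Protocol):
    """Contract: map an RNA window to its minimum free energy (<= 0)."""

    name: str

    def energy(self, window: str) -> float: ...

    def energies(self, seq: str, starts: np.ndarray, window: int) -> np.ndarray: ...


class NussinovEnergyBackend:
    """Built-in nested-structure MFE model (arbitrary energy units).

    Allowed pairs AU, GC, GU with energies -2, -3, -1; minimum hairpin
    loop of 3 unpaired bases; no pseudoknots.  Windows containing N yield
    NaN in batch mode and an error in single-window mode.
    """

    name = "nussinov-energy"

    def energy(self, window: str) -> float:
        arr = encode(window)
        if np.any(arr > 3):
            raise ValueError("window contains ambiguous bases (N)")
        return float(_fold_dp_nb(arr, _PAIR_E))

    def energies(self, seq: str, starts, window: int) -> np.ndarray:
        arr = encode(seq)
        starts = np.asarray(starts, dtype=np.int64)
        return _fold_windows_nb(arr, starts, window, _PAIR_E)

    def structure(self, window: str) -> tuple[float, str]:
        """Energy and one optimal dot-bracket structure (traceback)."""
        return fold_dp_reference(window)


class ViennaRNABackend:
    """Thermodynamic MFE via the ViennaRNA ``RNA`` bindings (kcal/mol)."""

    name = "viennarna"

    def __init__(self) -> None:
        import RNA  # noqa: F401 - import error surfaces at construction

        self._RNA = RNA

    def energy(self, window: str) -> float:
        if "N" in window.upper():
            raise ValueError("window contains ambiguous bases (N)")
        rna = window.upper().replace("T", "U")
        _, mfe = self._RNA.fold(rna)
        return min(float(mfe), 0.0)

    def energies(self, seq: str, starts, window: int) -> np.ndarray:
        out = np.empty(len(starts), dtype=float)
        for i, s in enumerate(np.asarray(starts, dtype=int)):
            sub = seq[s : s + window]
            out[i] = np.nan if "N" in sub.upper() else self.energy(sub)
        return out


def get_backend(name: str = "builtin") -> FoldingBackend:
    if name in ("builtin", NussinovEnergyBackend.name):
        return NussinovEnergyBackend()
    if name in ("vienna", ViennaRNABackend.name):
        return ViennaRNABackend()
    raise ValueError(f"unknown folding backend {name!r}")


# ---------------------------------------------------------------------------
# Windows and synonymous permutation
# ---------------------------------------------------------------------------

def sliding_windows(
    seq: str, window: int = DEFAULT_WINDOW, step: int = DEFAULT_STEP
) -> list[tuple[int, str]]:
    """All full windows [s, s+window) at s = 0, step, 2*step, ...; no
    partial tail windows.  Empty (with a warning) when the sequence is
    shorter than one window."""
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    if len(seq) < window:
        logger.warning(
            "sequence length %d shorter than window %d: no windows", len(seq), window
        )
        return []
    return [
        (s, seq[s : s + window]) for s in range(0, len(seq) - window + 1, step)
    ]


def window_starts(seq_len: int, window: int = DEFAULT_WINDOW, step: int = DEFAULT_STEP) -> np.ndarray:
    if seq_len < window:
        return np.empty(0, dtype=np.int64)
    return np.arange(0, seq_len - window + 1, step, dtype=np.int64)


def synonymous_permutation(cds: CodingSequence, seed=None) -> CodingSequence:
    """Uniform random shuffle of codons among positions encoding the same
    amino acid.  The protein and the codon multiset (hence nucleotide
    content) are exactly preserved.  Codons containing N stay in place."""
    rng = np.random.default_rng(seed)
    codons = cds.codons
    groups: dict[str, list[int]] = {}
    for i, c in enumerate(codons):
        if "N" in c:
            continue
        groups.setdefault(translate_codon(c), []).append(i)
    shuffled = list(codons)
    for positions in groups.values():
        if len(positions) < 2:
            continue
        perm = rng.permutation(len(positions))
        for dst, src in zip(positions, perm):
            shuffled[dst] = codons[positions[src]]
    out = CodingSequence(
        id=cds.id, seq="".join(shuffled), species=cds.species, gene=cds.gene
    )
    return out


def fold_mfe(window_rna: str, backend: FoldingBackend | None = None) -> float:
    """Minimum free energy of one window under the backend (default built-in)."""
    backend = backend or NussinovEnergyBackend()
    return backend.energy(window_rna)


# ---------------------------------------------------------------------------
# ΔLFE profiles
# ---------------------------------------------------------------------------

@dataclass
class LFEProfile:
    """Per-window native/permuted LFE and ΔLFE for one coding sequence."""

    gene: str
    species: str
    window: int
    step: int
    window_starts: np.ndarray
    native_lfe: np.ndarray
    permuted_mean_lfe: np.ndarray
    delta_lfe: np.ndarray
    x_intercepts_nt: list[float] = field(default_factory=list)
    ramp_codons: int = 0
    n_permutations: int = DEFAULT_N_PERMUTATIONS

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "gene": self.gene,
                "species": self.species,
                "window_start_nt": self.window_starts,
                "native_lfe": self.native_lfe,
                "permuted_mean_lfe": self.permuted_mean_lfe,
                "delta_lfe": self.delta_lfe,
            }
        )


@dataclass
class AggregateProfile:
    """Cross-species unweighted mean ΔLFE per window start for one gene."""

    gene: str
    window_starts: np.ndarray
    mean_delta_lfe: np.ndarray
    n_species: np.ndarray

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "gene": self.gene,
                "window_start_nt": self.window_starts,
                "mean_delta_lfe": self.mean_delta_lfe,
                "n_species": self.n_species,
            }
        )


def _crossings(starts: np.ndarray, values: np.ndarray) -> list[float]:
    """Sign-change positions of a piecewise-linear profile anchored at
    window starts; exact zeros are reported at their window start."""
    pts = [(float(s), float(v)) for s, v in zip(starts, values) if not math.isnan(v)]
    if len(pts) < 2:
        raise ValueError("need at least 2 valid windows for x-intercepts")
    out: list[float] = []
    for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
        if y0 == 0.0:
            if not out or out[-1] != x0:
                out.append(x0)
        elif y0 * y1 < 0.0:
            out.append(x0 + (x1 - x0) * (y0 / (y0 - y1)))
    if pts and pts[-1][1] == 0.0 and (not out or out[-1] != pts[-1][0]):
        out.append(pts[-1][0])
    return out


def x_intercepts(profile: "LFEProfile | tuple") -> list[float]:
    """Zero crossings (nt, linear interpolation) of a ΔLFE profile."""
    if isinstance(profile, LFEProfile):
        return _crossings(profile.window_starts, profile.delta_lfe)
    starts, values = profile
    return _crossings(np.asarray(starts, float), np.asarray(values, float))


def ramp_length_codons(
    starts: np.ndarray, values: np.ndarray, window: int
) -> int:
    """Length (in codons) of the 5' prefix of weaker-than-predicted
    structure: floor(first positive-to-negative ΔLFE crossing / 3).

    0 when the profile starts at or below zero; the full profile length in
    codons when ΔLFE never goes negative.
    """
    pts = [(float(s), float(v)) for s, v in zip(starts, values) if not math.isnan(v)]
    if not pts:
        raise ValueError("all-missing profile")
    full = int((pts[-1][0] + window) // 3)
    if pts[0][1] <= 0.0:
        return 0
    for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
        if y1 < 0.0 <= y0:
            x = x0 if y0 == 0.0 else x0 + (x1 - x0) * (y0 / (y0 - y1))
            return int(x // 3)
    return full


def delta_lfe_profile(
    cds: CodingSequence,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    backend: FoldingBackend | None = None,
    seed=None,
) -> LFEProfile:
    """ΔLFE profile of a CDS over the permutation null.

    Each permutation is a whole-sequence synonymous shuffle; its windows
    are extracted at the same coordinates as the native windows.  ΔLFE =
    native - mean(permuted).  Windows containing N are reported as NaN.
    Deterministic under a fixed seed.
    """
    if len(cds.seq) < window:
        raise ValueError(
            f"CDS {cds.id!r} shorter ({len(cds.seq)} nt) than one window ({window} nt)"
        )
    backend = backend or NussinovEnergyBackend()
    starts = window_starts(len(cds.seq), window, step)
    native = backend.energies(cds.seq, starts, window)

    rng = np.random.default_rng(seed)
    acc = np.zeros(len(starts))
    for _ in range(n_permutations):
        perm = synonymous_permutation(cds, seed=rng)
        acc += backend.energies(perm.seq, starts, window)
    perm_mean = acc / n_permutations
    delta = native - perm_mean

    profile = LFEProfile(
        gene=cds.gene,
        species=cds.species,
        window=window,
        step=step,
        window_starts=starts,
        native_lfe=native,
        permuted_mean_lfe=perm_mean,
        delta_lfe=delta,
        n_permutations=n_permutations,
    )
    valid = ~np.isnan(delta)
    if valid.sum() >= 2:
        profile.x_intercepts_nt = _crossings(starts, delta)
        profile.ramp_codons = ramp_length_codons(starts, delta, window)
    return profile


def aggregate_profiles(profiles: Sequence[LFEProfile]) -> AggregateProfile:
    """Unweighted mean ΔLFE per window start across species of one gene.

    Positions are aligned from the CDS start; a position appears as long
    as at least one species has a valid window there, with ``n_species``
    recording how many contributed.
    """
    if not profiles:
        raise ValueError("no profiles to aggregate")
    genes = {p.gene for p in profiles}
    if len(genes) > 1:
        raise ValueError(f"cannot aggregate mixed genes: {sorted(genes)}")
    by_start: dict[int, list[float]] = {}
    for p in profiles:
        for s, d in zip(p.window_starts, p.delta_lfe):
            if not math.isnan(d):
                by_start.setdefault(int(s), []).append(float(d))
    starts = np.array(sorted(by_start), dtype=np.int64)
    means = np.array([np.mean(by_start[s]) for s in starts])
    counts = np.array([len(by_start[s]) for s in starts], dtype=np.int64)
    return AggregateProfile(
        gene=profiles[0].gene,
        window_starts=starts,
        mean_delta_lfe=means,
        n_species=counts,
    )
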