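"""Codon-usage-bias metrics: effective number of codons (Nc), Codon
Adaptation Index (CAI), its random-synonymous-sequence expectation (eCAI),
GC3%, GC%, and the percent-difference normalizations used to compare a
domain against its whole-gene sequence.

Nc follows Wright's estimator: for each amino acid *a* with degeneracy
k >= 2 observed n_a >= 2 times, the codon homozygosity is estimated as

    F_a = (n_a * sum_i p_i**2 - 1) / (n_a - 1)

over the observed synonymous proportions p_i, averaged within each
degeneracy class, and

    Nc = N1 + N2/F2 + N3/F3 + N4/F4 + N6/F6

where N_k is the number of degeneracy-k amino acids observed in the
region.  Nc runs from 20 (a single codon per amino acid, maximal bias)
to 61 (uniform usage); the estimator can exceed 61 for finite samples
and is truncated there.  A weighted variant ("ncw", as used by the
CAIcal service) replaces the bias-corrected homozygosity with the plain
sum of squared pseudocounted proportions p_i = (n_i + 1)/(n_a + k).

CAI is the geometric mean of relative adaptiveness weights w_c over the
region's codons, excluding ATG, TGG and stops.  eCAI is an upper
tolerance bound on the CAI distribution of random synonymous sequences
encoding the same protein at the same GC content.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from ._codes import (
    DEGENERACY,
    SINGLE_CODON_AAS,
    STOP_CODONS,
    SYN_FAMILIES,
    gc_count,
    translate_codon,
)
from .seqio import (
    CodingSequence,
    CodonUsageTable,
    DomainPartition,
    Region,
    extract_region,
    whole_region,
)

logger = logging.getLogger(__name__)

NC_MAX = 61.0
NC_MIN = 20.0
CUB_NC_CUTOFF = 35.0

#: codons that never contribute to CAI
CAI_EXCLUDED = frozenset({"ATG", "TGG"}) | STOP_CODONS


def _codon_list(region) -> list[str]:
    """Sense codons of a region (terminal stop stripped, N-codons dropped)."""
    if isinstance(region, CodingSequence):
        codons = region.sense_codons
    else:
        codons = [c.upper().replace("U", "T") for c in region]
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
    return [c for c in codons if "N" not in c and c not in STOP_CODONS]


# ---------------------------------------------------------------------------
# Nc
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilyHomozygosity:
    """Homozygosity estimate for one synonymous family in one region."""

    amino_acid: str
    degeneracy: int
    n: int
    f_hat: float | None  # None when n < 2 or the estimate clamps to <= 0


@dataclass
class NcResult:
    value: float | None
    truncated: bool
    families: list[FamilyHomozygosity]
    warning: str | None = None


def _family_homozygosities(codons: Sequence[str], variant: str) -> list[FamilyHomozygosity]:
    counts_by_aa: dict[str, Counter] = {}
    for c in codons:
        counts_by_aa.setdefault(translate_codon(c), Counter())[c] += 1
    out = []
    for aa, counter in counts_by_aa.items():
        k = DEGENERACY[aa]
        if aa == "*" or k < 2:
            continue
        n = sum(counter.values())
        if variant == "ncw":
            # pseudocounted proportions over the full family
            probs = [(counter.get(c, 0) + 1) / (n + k) for c in SYN_FAMILIES[aa]]
            f_hat: float | None = sum(p * p for p in probs)
        else:
            if n < 2:
                f_hat = None
            else:
                sum_p2 = sum((m / n) ** 2 for m in counter.values())
                f_hat = (n * sum_p2 - 1) / (n - 1)
                if f_hat <= 0:  # small-sample artifact; treat as missing
                    f_hat = None
        out.append(FamilyHomozygosity(aa, k, n, f_hat))
    return out


def nc_details(region, variant: str = "wright") -> NcResult:
    """Effective number of codons with per-family diagnostics.

    ``variant`` is ``"wright"`` (default, bias-corrected homozygosity) or
    ``"ncw"`` (pseudocounted squared proportions).  Returns ``value=None``
    with a warning message when the estimator is undefined for the region
    (no degenerate family with n >= 2, or an observed degeneracy class
    other than k=3 with no usable family).
    """
    if variant not in {"wright", "ncw"}:
        raise ValueError(f"unknown Nc variant {variant!r}")
    codons = _codon_list(region)
    if not codons:
        return NcResult(None, False, [], warning="region has no countable codons")
    families = _family_homozygosities(codons, variant)

    n1 = sum(
        1 for c in set(codons) if translate_codon(c) in SINGLE_CODON_AAS
    )
    # mean homozygosity and amino-acid count per degeneracy class
    fbar: dict[int, float | None] = {}
    n_aas: dict[int, int] = {}
    for k in (2, 3, 4, 6):
        fams = [f for f in families if f.degeneracy == k]
        n_aas[k] = len(fams)
        valid = [f.f_hat for f in fams if f.f_hat is not None]
        fbar[k] = float(np.mean(valid)) if valid else None

    if all(fbar[k] is None for k in (2, 3, 4, 6)):
        return NcResult(
            None, False, families,
            warning="no degenerate family with enough codons for Nc",
        )
    if fbar[3] is None and n_aas[3] > 0:
        if fbar[2] is not None and fbar[4] is not None:
            fbar[3] = (fbar[2] + fbar[4]) / 2.0
    missing = [k for k in (2, 3, 4, 6) if n_aas[k] > 0 and fbar[k] is None]
    if missing:
        return NcResult(
            None, False, families,
            warning=f"degeneracy classes {missing} observed but unestimable",
        )
    value = float(n1) + sum(
        n_aas[k] / fbar[k] for k in (2, 3, 4, 6) if n_aas[k] > 0
    )
    truncated = value > NC_MAX
    return NcResult(min(value, NC_MAX), truncated, families)


def nc(region, variant: str = "wright") -> float | None:
    """Effective number of codons of a region (None when undefined)."""
    result = nc_details(region, variant=variant)
    if result.warning:
        logger.warning("nc: %s", result.warning)
    return result.value


def classify_cub(nc_value: float | None, cutoff: float = CUB_NC_CUTOFF) -> bool | None:
    """A region is flagged as codon-usage biased when Nc <= cutoff (35)."""
    if nc_value is None:
        return None
    return nc_value <= cutoff


# ---------------------------------------------------------------------------
# CAI
# ---------------------------------------------------------------------------

def cai(region, table: CodonUsageTable) -> float:
    """Codon Adaptation Index: geometric mean of w_c over contributing
    codons (ATG, TGG, stops and N-codons excluded)."""
    codons = [c for c in _codon_list(region) if c not in CAI_EXCLUDED]
    if not codons:
        raise ValueError("no codons contribute to CAI in this region")
    log_w = [math.log(table.weights[c]) for c in codons]
    return math.exp(sum(log_w) / len(log_w))


# ---------------------------------------------------------------------------
# eCAI
# ---------------------------------------------------------------------------

def _tilted_family_probs(aa: str, theta: float) -> np.ndarray:
    fam = SYN_FAMILIES[aa]
    w = np.array([theta ** gc_count(c) for c in fam], dtype=float)
    return w / w.sum()


def _expected_gc(protein: str, theta: float) -> float:
    """Expected GC fraction of a random synonymous sequence at tilt theta."""
    total = 0.0
    for aa in protein:
        p = _tilted_family_probs(aa, theta)
        gcs = np.array([gc_count(c) for c in SYN_FAMILIES[aa]], dtype=float)
        total += float(p @ gcs)
    return total / (3 * len(protein))


def _calibrate_theta(protein: str, gc_target: float, tol: float = 1e-6) -> float:
    """Bisection (on log theta) so that expected replicate GC == gc_target.

    Expected GC is monotone increasing in theta.  If the target lies
    outside the achievable synonymous range, theta is clamped to the
    bracket end with a warning.
    """
    lo, hi = -30.0, 30.0
    gc_lo = _expected_gc(protein, math.exp(lo))
    gc_hi = _expected_gc(protein, math.exp(hi))
    if gc_target <= gc_lo + tol:
        if gc_target < gc_lo - tol:
            warnings.warn("eCAI: query GC below achievable synonymous range; clamping")
        return math.exp(lo)
    if gc_target >= gc_hi - tol:
        if gc_target > gc_hi + tol:
            warnings.warn("eCAI: query GC above achievable synonymous range; clamping")
        return math.exp(hi)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        g = _expected_gc(protein, math.exp(mid))
        if abs(g - gc_target) < tol:
            return math.exp(mid)
        if g < gc_target:
            lo = mid
        else:
            hi = mid
    return math.exp(0.5 * (lo + hi))


def tolerance_factor(n: int, population: float, confidence: float) -> float:
    """One-sided normal tolerance k-factor via the noncentral t quantile."""
    z_p = stats.norm.ppf(population)
    return float(stats.nct.ppf(confidence, df=n - 1, nc=z_p * math.sqrt(n)) / math.sqrt(n))


def ecai_replicate_cais(
    region,
    table: CodonUsageTable,
    n_replicates: int = 500,
    seed=None,
) -> np.ndarray:
    """CAI values of random synonymous sequences matched to the region's
    protein and GC content (the eCAI null sample)."""
    codons = _codon_list(region)
    if not codons:
        raise ValueError("empty region")
    protein = "".join(translate_codon(c) for c in codons)
    gc_target = sum(gc_count(c) for c in codons) / (3 * len(codons))
    theta = _calibrate_theta(protein, gc_target)

    rng = np.random.default_rng(seed)
    # group positions by amino acid: the sampling law depends only on aa
    positions_by_aa: dict[str, list[int]] = {}
    for i, aa in enumerate(protein):
        positions_by_aa.setdefault(aa, []).append(i)

    log_w_sum = np.zeros(n_replicates)
    n_contrib = 0
    for aa, positions in sorted(positions_by_aa.items()):
        fam = SYN_FAMILIES[aa]
        contributing = [c for c in fam if c not in CAI_EXCLUDED]
        if not contributing:
            continue  # Met/Trp never contribute to CAI
        p = _tilted_family_probs(aa, theta)
        log_w = np.array([math.log(table.weights[c]) for c in fam])
        draws = rng.choice(len(fam), size=(n_replicates, len(positions)), p=p)
        log_w_sum += log_w[draws].sum(axis=1)
        n_contrib += len(positions)
    if n_contrib == 0:
        raise ValueError("no codons contribute to CAI in this region")
    return np.exp(log_w_sum / n_contrib)


def ecai(
    region,
    table: CodonUsageTable,
    n_replicates: int = 500,
    population: float = 0.90,
    confidence: float = 0.90,
    seed=None,
) -> float:
    """Expected CAI: upper one-sided normal tolerance bound m + k*s covering
    ``population`` of the random-synonymous-sequence CAI distribution with
    the given ``confidence``.  Deterministic under a fixed seed."""
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    codons = _codon_list(region)
    if not codons:
        raise ValueError("empty region")
    protein = "".join(translate_codon(c) for c in codons)
    if not any(DEGENERACY[aa] > 1 for aa in protein):
        # no synonymous freedom: every replicate is the native sequence, so
        # eCAI coincides with the native CAI (and shares its domain errors)
        return cai(region, table)
    reps = ecai_replicate_cais(region, table, n_replicates=n_replicates, seed=seed)
    m = float(reps.mean())
    s = float(reps.std(ddof=1))
    if s == 0.0:
        return min(m, 1.0)
    k = tolerance_factor(n_replicates, population, confidence)
    return min(m + k * s, 1.0)


# ---------------------------------------------------------------------------
# GC composition
# ---------------------------------------------------------------------------

def gc3(region) -> float:
    """Percent of codons with G or C at the third position (stops excluded,
    ATG/TGG included)."""
    codons = _codon_list(region)
    if not codons:
        raise ValueError("no codons to compute GC3 over")
    hits = sum(1 for c in codons if c[2] in "GC")
    return 100.0 * hits / len(codons)


def gc(region) -> float:
    """Percent G+C over the region's nucleotides (stop codon and N excluded)."""
    codons = _codon_list(region)
    nts = "".join(codons)
    if not nts:
        raise ValueError("no nucleotides to compute GC over")
    hits = sum(1 for b in nts if b in "GC")
    return 100.0 * hits / len(nts)


def percent_difference(value: float, reference: float) -> float:
    """100 * (value - reference) / reference.

    Used both for domain-vs-whole-gene normalization and for the CAI-vs-eCAI
    comparison (positive: more frequent codons than expected; negative: more
    rare codons).  Undefined (NaN, with a warning) for zero reference.
    """
    if reference == 0:
        warnings.warn("percent_difference: zero reference value")
        return float("nan")
    return 100.0 * (value - reference) / reference


# ---------------------------------------------------------------------------
# Per-region report
# ---------------------------------------------------------------------------

FIRST_N_REGION_NAME = "first{n}"


@dataclass
class CUBReport:
    """All codon-usage metrics for one region of one coding sequence."""

    gene: str
    species: str
    region_name: str
    n_codons: int
    nc: float | None = None
    nc_variant: str = "wright"
    nc_truncated: bool = False
    cai: float | None = None
    ecai: float | None = None
    cai_vs_ecai_pct: float | None = None
    gc3_pct: float | None = None
    gc_pct: float | None = None
    nc_norm_pct: float | None = None
    gc3_norm_pct: float | None = None
    gc_norm_pct: float | None = None
    cub_flag: bool | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "gene": self.gene,
            "species": self.species,
            "region": self.region_name,
            "n_codons": self.n_codons,
            "nc": self.nc,
            "nc_variant": self.nc_variant,
            "cai": self.cai,
            "ecai": self.ecai,
            "cai_vs_ecai_pct": self.cai_vs_ecai_pct,
            "gc3_pct": self.gc3_pct,
            "gc_pct": self.gc_pct,
            "nc_norm_pct": self.nc_norm_pct,
            "gc3_norm_pct": self.gc3_norm_pct,
            "gc_norm_pct": self.gc_norm_pct,
            "cub_flag": self.cub_flag,
        }
        return d


def _metrics_for(region_cds, table, params, seed) -> dict:
    out: dict = {"notes": []}
    try:
        res = nc_details(region_cds, variant=params.get("nc_variant", "wright"))
        out["nc"], out["nc_truncated"] = res.value, res.truncated
        if res.warning:
            out["notes"].append(res.warning)
    except ValueError as exc:
        out["nc"] = None
        out["notes"].append(str(exc))
    for key, fn in (("cai", cai), ("gc3_pct", gc3), ("gc_pct", gc)):
        try:
            out[key] = fn(region_cds, table) if key == "cai" else fn(region_cds)
        except ValueError as exc:
            out[key] = None
            out["notes"].append(f"{key}: {exc}")
    try:
        out["ecai"] = ecai(
            region_cds,
            table,
            n_replicates=params.get("ecai_replicates", 500),
            population=params.get("ecai_population", 0.90),
            confidence=params.get("ecai_confidence", 0.90),
            seed=seed,
        )
    except ValueError as exc:
        out["ecai"] = None
        out["notes"].append(f"ecai: {exc}")
    return out


def region_report(
    cds: CodingSequence,
    partition: DomainPartition,
    table: CodonUsageTable,
    params: dict | None = None,
    seed=None,
) -> list[CUBReport]:
    """One CUBReport per partition region, plus the whole-gene region and
    (when ``params['first_n']`` is set) the first-N-codons region.

    Normalized percent differences are computed against the whole-gene
    values.  Per-metric failures are recorded as missing fields; the report
    itself never aborts.
    """
    params = dict(params or {})
    first_n = params.get("first_n", 10)
    cutoff = params.get("cub_cutoff", CUB_NC_CUTOFF)
    nc_variant = params.get("nc_variant", "wright")
    partition.validate_against(cds)

    regions: list[Region] = [whole_region(cds)] + list(partition.regions)
    if first_n:
        n = min(first_n, len(cds.sense_codons))
        regions.append(Region(FIRST_N_REGION_NAME.format(n=first_n), 0, n))

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(regions))
    reports: list[CUBReport] = []
    whole_metrics: dict | None = None
    for region, child in zip(regions, children):
        region_cds = extract_region(cds, region)
        m = _metrics_for(region_cds, table, params, seed=child)
        rep = CUBReport(
            gene=cds.gene,
            species=cds.species,
            region_name=region.name,
            n_codons=region.end - region.start,
            nc=m["nc"],
            nc_variant=nc_variant,
            nc_truncated=m.get("nc_truncated", False),
            cai=m["cai"],
            ecai=m["ecai"],
            gc3_pct=m["gc3_pct"],
            gc_pct=m["gc_pct"],
            notes=m["notes"],
        )
        if rep.cai is not None and rep.ecai is not None:
            rep.cai_vs_ecai_pct = percent_difference(rep.cai, rep.ecai)
        rep.cub_flag = classify_cub(rep.nc, cutoff=cutoff)
        if region.name == "whole":
            whole_metrics = m
            rep.nc_norm_pct = rep.gc3_norm_pct = rep.gc_norm_pct = 0.0
        elif whole_metrics is not None:
            for src, dst in (("nc", "nc_norm_pct"), ("gc3_pct", "gc3_norm_pct"), ("gc_pct", "gc_norm_pct")):
                dom, ref = m[src], whole_metrics[src]
                if dom is not None and ref not in (None, 0):
                    setattr(rep, dst, percent_difference(dom, ref))
        reports.append(rep)
    return reports


def reports_to_frame(reports: Iterable[CUBReport]):
    """Tidy DataFrame with one row per (gene, species, region)."""
    import pandas as pd

    return pd.DataFrame([r.to_dict() for r in reports])
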