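"""Synthetic multi-species homolog sets with controlled codon-usage
structure.

The generator emulates the statistical features the analysis is designed
to detect in a vertebrate gene family: per-domain codon-bias contrasts
(rare-codon 5' ramps, GC3-elevated domains), species-specific codon
usage tables, designed 5' hairpins that synonymous alternatives disrupt,
and variant lists with fixed class quotas.  Cross-species homologs share
the protein exactly (no amino-acid divergence), isolating the
synonymous-level signal.  Everything is deterministic under a seed and
emitted in the same file formats as real inputs (FASTA, Kazusa tables,
partition YAML, variant TSV).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from ._codes import SENSE_CODONS, SINGLE_CODON_AAS, SYN_FAMILIES, revcomp, translate_codon
from .seqio import (
    CodingSequence,
    CodonUsageTable,
    DomainPartition,
    Region,
    VariantRecord,
    write_codon_table,
    write_fasta,
    write_partition,
    write_variants,
)
from .variants import MISSENSE, NONSENSE, SYNONYMOUS, classify_substitution

logger = logging.getLogger(__name__)

AMINO_ACIDS = sorted(aa for aa in SYN_FAMILIES if aa != "*")

#: floor applied to weights when sampling rare codons (mirrors the
#: pseudo-frequency floor used when deriving weights)
RARE_WEIGHT_FLOOR = 0.05
FREQUENT_ARGMAX_PROB = 0.9


@dataclass(frozen=True)
class RegionBias:
    """Codon-sampling law for one region: 'frequent', 'rare', 'uniform' or
    'gc3_tilted' (with an explicit tilt theta or a target GC3 fraction)."""

    sampling: str = "uniform"
    theta: float | None = None
    target_gc3: float | None = None

    def __post_init__(self) -> None:
        if self.sampling not in {"frequent", "rare", "uniform", "gc3_tilted"}:
            raise ValueError(f"unknown sampling mode {self.sampling!r}")
        if self.sampling == "gc3_tilted" and self.theta is None and self.target_gc3 is None:
            raise ValueError("gc3_tilted requires theta or target_gc3")


@dataclass(frozen=True)
class HairpinSpec:
    """A designed stem-loop: ``start_nt`` (codon-aligned), stem and loop
    lengths in nt.  The loop is padded so the segment ends on a codon
    boundary."""

    start_nt: int
    stem_len: int
    loop_len: int

    def __post_init__(self) -> None:
        if self.stem_len < 3 or self.loop_len < 3:
            raise ValueError("stem_len and loop_len must each be >= 3")
        if self.start_nt < 0 or self.start_nt % 3 != 0:
            raise ValueError("start_nt must be a non-negative codon boundary")


@dataclass
class BiasProfile:
    """Region-wise codon-sampling plan for one gene; regions must tile the
    coding sequence."""

    regions: list[tuple[Region, RegionBias]]
    hairpin: HairpinSpec | None = None

    def validate(self, n_codons: int) -> None:
        ordered = sorted(self.regions, key=lambda rb: rb[0].start)
        cursor = 0
        for region, _ in ordered:
            if region.start != cursor:
                raise ValueError(
                    f"bias regions do not tile the gene: gap/overlap at codon {cursor}"
                )
            cursor = region.end
        if cursor != n_codons:
            raise ValueError(
                f"bias regions cover [0,{cursor}) but gene has {n_codons} codons"
            )

    def bias_at(self, codon_index: int) -> RegionBias:
        for region, bias in self.regions:
            if region.start <= codon_index < region.end:
                return bias
        raise IndexError(codon_index)

    @classmethod
    def uniform(cls, n_codons: int) -> "BiasProfile":
        return cls(regions=[(Region("all", 0, n_codons), RegionBias("uniform"))])


# ---------------------------------------------------------------------------
# Codon usage tables
# ---------------------------------------------------------------------------

def make_codon_table(species_label: str, skew: float = 2.0, seed=None) -> CodonUsageTable:
    """Random species codon usage table.

    Within every synonymous family, frequencies are Dirichlet draws with
    concentration 1/(1+skew): higher skew concentrates usage on fewer
    codons per family.  Family totals are proportional to family size so
    the table sums to 1000 per thousand; counts are scaled to a nominal
    million codons.
    """
    if skew < 0:
        raise ValueError("skew must be >= 0")
    rng = np.random.default_rng(seed)
    alpha = 1.0 / (1.0 + skew)
    freq: dict[str, float] = {}
    for aa, family in sorted(SYN_FAMILIES.items()):
        k = len(family)
        total = 1000.0 * k / 64.0
        if k == 1:
            freq[family[0]] = total
            continue
        p = rng.dirichlet([alpha] * k)
        for codon, pi in zip(family, p):
            # 4 decimals: matches the table writer so files round-trip exactly
            freq[codon] = round(total * float(pi), 4)
    counts = {c: int(round(f * 1000)) for c, f in freq.items()}
    return CodonUsageTable(species=species_label, freq_per_thousand=freq, counts=counts)


# ---------------------------------------------------------------------------
# Codon sampling laws
# ---------------------------------------------------------------------------

def _family_probs(aa: str, bias: RegionBias, table: CodonUsageTable, theta: float | None) -> np.ndarray:
    family = SYN_FAMILIES[aa]
    k = len(family)
    if k == 1:
        return np.ones(1)
    if bias.sampling == "uniform":
        return np.full(k, 1.0 / k)
    if bias.sampling == "frequent":
        w = np.array([table.weights[c] for c in family])
        p = np.full(k, (1.0 - FREQUENT_ARGMAX_PROB) / (k - 1))
        p[int(np.argmax(w))] = FREQUENT_ARGMAX_PROB
        return p
    if bias.sampling == "rare":
        w = np.array([max(table.weights[c], RARE_WEIGHT_FLOOR) for c in family])
        p = 1.0 / w
        return p / p.sum()
    # gc3_tilted
    t = theta if theta is not None else bias.theta
    tilt = np.array([t if c[2] in "GC" else 1.0 for c in family])
    return tilt / tilt.sum()


def _expected_gc3(protein: str, theta: float) -> float:
    total = 0.0
    for aa in protein:
        family = SYN_FAMILIES[aa]
        tilt = np.array([theta if c[2] in "GC" else 1.0 for c in family])
        p = tilt / tilt.sum()
        total += float(sum(pi for pi, c in zip(p, family) if c[2] in "GC"))
    return total / len(protein)


def _calibrate_gc3_theta(protein: str, target: float, tol: float = 1e-6) -> float:
    """Bisection on log(theta) so expected GC3 fraction equals ``target``
    (clamped to the achievable range)."""
    lo, hi = -30.0, 30.0
    g_lo, g_hi = _expected_gc3(protein, np.exp(lo)), _expected_gc3(protein, np.exp(hi))
    if target <= g_lo:
        return float(np.exp(lo))
    if target >= g_hi:
        return float(np.exp(hi))
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        g = _expected_gc3(protein, np.exp(mid))
        if abs(g - target) < tol:
            break
        if g < target:
            lo = mid
        else:
            hi = mid
    return float(np.exp(0.5 * (lo + hi)))


# ---------------------------------------------------------------------------
# Hairpin design
# ---------------------------------------------------------------------------

def _design_hairpin(spec: HairpinSpec, rng: np.random.Generator, max_attempts: int = 50) -> str:
    """Nucleotide segment ``stem + loop + revcomp(stem)`` padded with A to a
    codon boundary.  Stems are G/C-only, so the segment is stop-free in
    frame and strongly paired; synonymous shuffles of the embedding gene
    disrupt the stem.  Retries (bounded) if an in-frame stop appears."""
    for _ in range(max_attempts):
        stem = "".join(rng.choice(["G", "C"], size=spec.stem_len))
        loop = "A" * spec.loop_len
        seg = stem + loop + revcomp(stem)
        if len(seg) % 3:
            seg = seg + "A" * (3 - len(seg) % 3)
        codons = [seg[i : i + 3] for i in range(0, len(seg), 3)]
        if all(translate_codon(c) != "*" for c in codons):
            return seg
    raise RuntimeError("could not realize a stop-free hairpin segment")


# ---------------------------------------------------------------------------
# Homolog sets
# ---------------------------------------------------------------------------

@dataclass
class HomologSet:
    """One gene's synthetic homologs: shared protein, per-species CDS and
    codon usage tables."""

    gene: str
    protein: str
    sequences: dict[str, CodingSequence]
    tables: dict[str, CodonUsageTable]
    bias: BiasProfile = field(repr=False, default=None)


def generate_homolog_set(
    protein_len: int,
    n_species: int,
    bias: BiasProfile | None = None,
    seed=None,
    gene: str = "geneA",
    skew: float = 2.0,
    tables: Mapping[str, CodonUsageTable] | None = None,
    species_labels: Sequence[str] | None = None,
) -> HomologSet:
    """Draw one protein and emit one CDS per species, sampling each
    residue's codon from the region's bias law against that species'
    usage table.  A hairpin spec overrides the covered codons with the
    designed nucleotides (identical across species)."""
    if protein_len < 2:
        raise ValueError("protein_len must be >= 2")
    bias = bias or BiasProfile.uniform(protein_len)
    bias.validate(protein_len)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss_protein, ss_tables, ss_sample = ss.spawn(3)
    rng_protein = np.random.default_rng(ss_protein)
    rng_sample = np.random.default_rng(ss_sample)

    # protein: Met start, then uniform over the 20 amino acids
    protein = ["M"] + list(rng_protein.choice(AMINO_ACIDS, size=protein_len - 1))

    hairpin_codons: dict[int, str] = {}
    if bias.hairpin is not None:
        seg = _design_hairpin(bias.hairpin, rng_protein)
        c0 = bias.hairpin.start_nt // 3
        n_seg = len(seg) // 3
        if c0 + n_seg > protein_len:
            raise ValueError("hairpin extends beyond the gene")
        if c0 == 0:
            raise ValueError("hairpin cannot overwrite the initiator codon")
        for i in range(n_seg):
            codon = seg[3 * i : 3 * i + 3]
            hairpin_codons[c0 + i] = codon
            protein[c0 + i] = translate_codon(codon)
    protein = "".join(protein)

    if species_labels is None:
        species_labels = [f"sp{i + 1:02d}" for i in range(n_species)]
    if tables is None:
        tables = {
            sp: make_codon_table(sp, skew=skew, seed=s)
            for sp, s in zip(species_labels, ss_tables.spawn(len(species_labels)))
        }

    sequences: dict[str, CodingSequence] = {}
    for sp in species_labels:
        table = tables[sp]
        # resolve gc3 tilt per region for this species' protein stretch
        thetas: dict[int, float | None] = {}
        for idx, (region, rbias) in enumerate(bias.regions):
            if rbias.sampling == "gc3_tilted" and rbias.theta is None:
                sub = protein[region.start : region.end]
                thetas[idx] = _calibrate_gc3_theta(sub, rbias.target_gc3)
            else:
                thetas[idx] = rbias.theta
        codons: list[str] = []
        for i, aa in enumerate(protein):
            if i in hairpin_codons:
                codons.append(hairpin_codons[i])
                continue
            for idx, (region, rbias) in enumerate(bias.regions):
                if region.start <= i < region.end:
                    break
            family = SYN_FAMILIES[aa]
            p = _family_probs(aa, rbias, table, thetas[idx])
            codons.append(family[int(rng_sample.choice(len(family), p=p))])
        codons.append("TAA")  # terminal stop
        sequences[sp] = CodingSequence(
            id=f"{gene}_{sp}", seq="".join(codons), species=sp, gene=gene
        )
    return HomologSet(gene=gene, protein=protein, sequences=sequences, tables=dict(tables), bias=bias)


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

def generate_variants(
    cds: CodingSequence,
    n_syn: int,
    n_mis: int,
    n_non: int,
    seed=None,
    max_attempts_per_variant: int = 2000,
) -> list[VariantRecord]:
    """Rejection-sample single-nucleotide substitutions until each class
    quota (synonymous, missense, nonsense) is met.  Errors if a quota is
    unachievable within the attempt budget."""
    rng = np.random.default_rng(seed)
    quotas = {SYNONYMOUS: n_syn, MISSENSE: n_mis, NONSENSE: n_non}
    total = n_syn + n_mis + n_non
    chosen: list[VariantRecord] = []
    used: set[tuple[int, str]] = set()
    attempts = 0
    budget = max_attempts_per_variant * max(total, 1)
    while sum(quotas.values()) > 0:
        attempts += 1
        if attempts > budget:
            raise RuntimeError(
                f"variant quotas unachievable on {cds.id!r}: remaining {quotas}"
            )
        pos = int(rng.integers(0, len(cds.seq)))
        ref = cds.seq[pos]
        if ref == "N":
            continue
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        if (pos, alt) in used:
            continue
        v = VariantRecord(pos, ref, alt)
        cls = classify_substitution(cds, v)
        if quotas.get(cls, 0) > 0:
            quotas[cls] -= 1
            used.add((pos, alt))
            chosen.append(v)
    return sorted(chosen, key=lambda v: (v.cds_position, v.alt))


# ---------------------------------------------------------------------------
# B56-like preset
# ---------------------------------------------------------------------------

B56LIKE_GENES = ("B56a", "B56b", "B56g", "B56d", "B56e")


def b56like_bias(gene: str, protein_len: int) -> BiasProfile:
    """Bias plan emulating the study's per-gene contrasts: one isoform with
    a rare-codon first-ten ramp, a GC3-elevated N-terminal domain and a
    designed 5' hairpin; one with a frequent-codon N-terminus; one with a
    GC3-elevated N-terminus; the rest unbiased."""
    if protein_len < 75:
        raise ValueError("b56like profiles need protein_len >= 75 (ramp, hairpin and domains must fit)")
    n_term = protein_len // 5
    rest = [
        (Region("core", n_term, protein_len - n_term), RegionBias("uniform")),
        (Region("cterm", protein_len - n_term, protein_len), RegionBias("uniform")),
    ]
    if gene == "B56a":
        # rare-codon ramp against a frequent-codon body, so first-ten CAI
        # sits below the whole-gene CAI; GC3-elevated N-terminal remainder;
        # designed 5' hairpin
        return BiasProfile(
            regions=[
                (Region("ramp", 0, 10), RegionBias("rare")),
                (Region("nterm_rest", 10, n_term), RegionBias("gc3_tilted", target_gc3=0.80)),
                (Region("core", n_term, protein_len - n_term), RegionBias("frequent")),
                (Region("cterm", protein_len - n_term, protein_len), RegionBias("frequent")),
            ],
            hairpin=HairpinSpec(start_nt=30, stem_len=12, loop_len=6),
        )
    if gene == "B56b":
        return BiasProfile(
            regions=[(Region("nterm", 0, n_term), RegionBias("frequent"))] + rest
        )
    if gene == "B56g":
        return BiasProfile(
            regions=[(Region("nterm", 0, n_term), RegionBias("gc3_tilted", target_gc3=0.85))] + rest
        )
    return BiasProfile(
        regions=[(Region("nterm", 0, n_term), RegionBias("uniform"))] + rest
    )


def default_partition(n_codons: int) -> DomainPartition:
    """N-terminus / core / C-terminus split at 20% / 60% / 20%."""
    n_term = n_codons // 5
    return DomainPartition(
        [
            Region("nterm", 0, n_term),
            Region("core", n_term, n_codons - n_term),
            Region("cterm", n_codons - n_term, n_codons),
        ]
    )


def b56like_preset(
    out_dir,
    n_species: int = 28,
    protein_len: int = 500,
    seed=20231227,
    genes: Sequence[str] = B56LIKE_GENES,
) -> dict:
    """Write a complete synthetic study to ``out_dir``: per-gene FASTA
    (one record per species), per-species Kazusa tables shared across
    genes, a partition YAML, a variant TSV for the first gene, and a
    ready-to-run pipeline config.  Returns the config as a dict."""
    out = Path(out_dir)
    (out / "genes").mkdir(parents=True, exist_ok=True)
    (out / "tables").mkdir(exist_ok=True)
    ss = np.random.SeedSequence(seed)
    table_seeds, *gene_seeds = ss.spawn(1 + len(genes))
    species = [f"sp{i + 1:02d}" for i in range(n_species)]
    tables = {
        sp: make_codon_table(sp, skew=2.0, seed=s)
        for sp, s in zip(species, table_seeds.spawn(n_species))
    }
    for sp, table in tables.items():
        write_codon_table(table, out / "tables" / f"{sp}.txt")

    fasta_paths: dict[str, str] = {}
    first_cds = None
    for gene, gseed in zip(genes, gene_seeds):
        hs = generate_homolog_set(
            protein_len,
            n_species,
            bias=b56like_bias(gene, protein_len),
            seed=gseed,
            gene=gene,
            tables=tables,
            species_labels=species,
        )
        path = out / "genes" / f"{gene}.fasta"
        write_fasta([hs.sequences[sp] for sp in species], path)
        fasta_paths[gene] = str(path)
        if first_cds is None:
            first_cds = hs.sequences[species[0]]

    partition = default_partition(protein_len)
    write_partition(partition, out / "partition.yaml")

    var_seed = int(np.random.default_rng(ss.spawn(1)[0]).integers(0, 2**31 - 1))
    variants = generate_variants(first_cds, n_syn=5, n_mis=9, n_non=2, seed=var_seed)
    write_variants(variants, out / f"{genes[0]}_variants.tsv")

    config = {
        "genes": fasta_paths,
        "codon_tables": {sp: str(out / "tables" / f"{sp}.txt") for sp in species},
        "partition": str(out / "partition.yaml"),
        "outdir": str(out / "results"),
        "params": {"seed": int(np.random.SeedSequence(seed).generate_state(1)[0] % 2**31)},
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    logger.info(
        "b56like preset: %d genes x %d species, %d codons -> %s",
        len(genes), n_species, protein_len, out,
    )
    return config
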