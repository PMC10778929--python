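"""Input/output and validation for coding sequences, codon usage tables,
domain partitions, alignments and variant lists.

Conventions used throughout the package:

* coordinates are 0-based and half-open, in **codon** units (nucleotide
  coordinates appear only in the folding module, also 0-based half-open);
* the internal alphabet is DNA; RNA input (``U``) is transcribed on entry;
* the terminal stop codon is stripped before any codon-usage metric.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from Bio import SeqIO

from ._codes import CODONS, STOP_CODONS, translate_codon

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; message names the offending line."""


class InvalidSequenceError(ValueError):
    """Raised when a record violates coding-sequence invariants."""


@dataclass
class CodingSequence:
    """One species' coding sequence (CDS) for one gene/isoform.

    Validated on construction: DNA alphabet (plus N), length divisible by 3,
    and no internal stop codon in frame 0 (a terminal stop is permitted).
    """

    id: str
    seq: str
    species: str = ""
    gene: str = ""

    def __post_init__(self) -> None:
        self.seq = self.seq.upper().replace("U", "T")
        bad = set(self.seq) - _VALID_BASES
        if bad:
            raise InvalidSequenceError(
                f"record {self.id!r}: invalid characters {sorted(bad)}"
            )
        if len(self.seq) % 3 != 0:
            raise InvalidSequenceError(
                f"record {self.id!r}: length {len(self.seq)} not divisible by 3"
            )
        codons = self.codons
        for i, codon in enumerate(codons[:-1]):
            if codon in STOP_CODONS:
                raise InvalidSequenceError(
                    f"record {self.id!r}: internal stop codon {codon} at codon {i}"
                )

    @property
    def codons(self) -> list[str]:
        return [self.seq[i : i + 3] for i in range(0, len(self.seq), 3)]

    @property
    def n_codons(self) -> int:
        return len(self.seq) // 3

    @property
    def has_terminal_stop(self) -> bool:
        return self.n_codons > 0 and self.seq[-3:] in STOP_CODONS

    @property
    def sense_codons(self) -> list[str]:
        """Codon list with the terminal stop (if any) stripped."""
        codons = self.codons
        if self.has_terminal_stop:
            codons = codons[:-1]
        return codons

    @property
    def protein(self) -> str:
        """Translation of the sense codons ('X' for N-containing codons)."""
        return "".join(translate_codon(c) for c in self.sense_codons)


@dataclass(frozen=True)
class Region:
    """Named codon-coordinate region, 0-based half-open."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"region {self.name!r}: need 0 <= start < end")


WHOLE_REGION_NAME = "whole"


@dataclass
class DomainPartition:
    """Ordered, non-overlapping named codon regions (e.g. N-terminus, core,
    C-terminus).  The whole-gene region is implicit and always available."""

    regions: list[Region]

    def __post_init__(self) -> None:
        self.regions = [
            r if isinstance(r, Region) else Region(*r) for r in self.regions
        ]
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate region names in partition: {names}")
        if WHOLE_REGION_NAME in names:
            raise ValueError(f"region name {WHOLE_REGION_NAME!r} is reserved")
        ordered = sorted(self.regions, key=lambda r: r.start)
        for a, b in zip(ordered, ordered[1:]):
            if a.end > b.start:
                raise ValueError(f"regions {a.name!r} and {b.name!r} overlap")

    def validate_against(self, cds: CodingSequence) -> None:
        n = len(cds.sense_codons)
        for r in self.regions:
            if r.end > n:
                raise ValueError(
                    f"region {r.name!r} [{r.start},{r.end}) exceeds "
                    f"{n} sense codons of {cds.id!r}"
                )

    @classmethod
    def from_dict(cls, entries: Iterable[Mapping]) -> "DomainPartition":
        return cls(
            [Region(str(e["name"]), int(e["start"]), int(e["end"])) for e in entries]
        )


@dataclass
class AlignedSet:
    """A gapped amino-acid alignment for one gene: species -> row."""

    gene: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"alignment rows of unequal length: {sorted(lengths)}")


@dataclass(frozen=True)
class VariantRecord:
    """A single-nucleotide substitution in CDS coordinates (0-based)."""

    cds_position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(
                "only single-nucleotide substitutions are supported "
                f"(got ref={self.ref!r}, alt={self.alt!r})"
            )
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.cds_position}")
        if self.cds_position < 0:
            raise ValueError(f"negative CDS position {self.cds_position}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, on_invalid: str = "raise") -> list[CodingSequence]:
    """Read coding sequences from a (multi-)FASTA file.

    Headers of the form ``gene|species|id`` are split into the three fields;
    any other header becomes the record id.  Sequences are uppercased and
    U is transcribed to T.  Records violating the CDS invariants raise
    (``on_invalid='raise'``) or are skipped with a warning
    (``on_invalid='skip'``).
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: expected '>' header, got {line[:30]!r}"
                    )
                break
    out: list[CodingSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description or rec.id
        parts = header.split("|")
        if len(parts) == 3:
            gene, species, rec_id = (p.strip() for p in parts)
        else:
            gene, species, rec_id = "", "", header.strip()
        try:
            out.append(
                CodingSequence(id=rec_id, seq=str(rec.seq), species=species, gene=gene)
            )
        except InvalidSequenceError as exc:
            if on_invalid == "skip":
                logger.warning("skipping invalid record: %s", exc)
            else:
                raise
    return out


def write_fasta(seqs: Sequence[CodingSequence], path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            header = f"{s.gene}|{s.species}|{s.id}" if s.gene or s.species else s.id
            fh.write(f">{header}\n")
            for i in range(0, len(s.seq), 70):
                fh.write(s.seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Codon usage tables (Kazusa Codon Usage Database text format)
# ---------------------------------------------------------------------------

_KAZUSA_FIELD = re.compile(r"([ACGU]{3})\s+([0-9.]+)\s*\(\s*([0-9]+)\s*\)")


@dataclass
class CodonUsageTable:
    """Per-codon reference usage for one species.

    ``freq_per_thousand`` holds the codon frequencies f_c per 1000 codons;
    ``counts`` the raw occurrence counts when known.  ``weights`` holds the
    relative adaptiveness w_c = f_c / max(f) within each synonymous family,
    recomputed from the frequencies alone (idempotent).  Stop codons carry
    frequencies but no weights.  Zero-frequency codons receive a
    pseudo-frequency (0.5 occurrences on the table's count scale when counts
    are known, otherwise half the smallest positive entry) so that every
    weight is strictly positive.
    """

    species: str
    freq_per_thousand: dict[str, float]
    counts: dict[str, int] | None = None
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CODONS if c not in self.freq_per_thousand]
        if missing:
            raise ValueError(
                f"codon table for {self.species!r} missing {len(missing)} "
                f"codons: {missing[:6]}{'...' if len(missing) > 6 else ''}"
            )
        negative = [c for c, f in self.freq_per_thousand.items() if f < 0]
        if negative:
            raise ValueError(f"negative frequencies for codons {negative}")
        self.recompute_weights()

    def _pseudo_freq(self) -> float:
        if self.counts:
            total = sum(self.counts.values())
            if total > 0:
                return 0.5 / total * 1000.0
        positive = [f for f in self.freq_per_thousand.values() if f > 0]
        return min(positive) / 2.0 if positive else 1.0

    def recompute_weights(self) -> None:
        """Derive w_c from freq_per_thousand (max weight per family == 1)."""
        from ._codes import SYN_FAMILIES  # local import avoids cycle at init

        pseudo = self._pseudo_freq()
        weights: dict[str, float] = {}
        for aa, family in SYN_FAMILIES.items():
            if aa == "*":
                continue
            freqs = {
                c: (self.freq_per_thousand[c] if self.freq_per_thousand[c] > 0 else pseudo)
                for c in family
            }
            fmax = max(freqs.values())
            for c, f in freqs.items():
                weights[c] = f / fmax
        self.weights = weights


def read_codon_table(path, species: str | None = None) -> CodonUsageTable:
    """Parse a Kazusa-format codon usage table.

    Accepts the standard ``CODON  freq  (count)`` fields, several per line,
    in the RNA alphabet.  The species label defaults to the file stem.
    """
    path = Path(path)
    text = path.read_text()
    freq: dict[str, float] = {}
    counts: dict[str, int] = {}
    for m in _KAZUSA_FIELD.finditer(text):
        codon = m.group(1).replace("U", "T")
        freq[codon] = float(m.group(2))
        counts[codon] = int(m.group(3))
    return CodonUsageTable(
        species=species or path.stem, freq_per_thousand=freq, counts=counts
    )


def write_codon_table(table: CodonUsageTable, path) -> None:
    """Write a table back out in Kazusa style (4 fields per line, RNA).

    Frequencies are written at 4 decimals, so tables whose entries carry at
    most 4 decimals (Kazusa files, the synthetic generator) round-trip
    exactly.
    """
    fields = []
    for codon in CODONS:
        f = table.freq_per_thousand[codon]
        n = table.counts.get(codon, 0) if table.counts else 0
        fields.append(f"{codon.replace('T', 'U')} {f:.4f} ({n})")
    with open(path, "w") as fh:
        for i in range(0, len(fields), 4):
            fh.write("  ".join(fields[i : i + 4]) + "\n")


# ---------------------------------------------------------------------------
# Alignment gap filter
# ---------------------------------------------------------------------------

def max_gap_run(row: str) -> int:
    """Length of the longest contiguous run of '-' in an alignment row."""
    best = 0
    for m in re.finditer(r"-+", row):
        best = max(best, m.end() - m.start())
    return best


def filter_by_gap(aligned: AlignedSet, max_gap_run_len: int = 60) -> AlignedSet:
    """Drop alignment rows containing a contiguous gap run of
    ``max_gap_run_len`` or more residues (sequence-quality filter)."""
    if not aligned.rows:
        raise ValueError("empty alignment")
    kept: dict[str, str] = {}
    for species, row in aligned.rows.items():
        if max_gap_run(row) >= max_gap_run_len:
            logger.warning(
                "filter_by_gap: excluding %s (%s): gap run >= %d",
                species, aligned.gene, max_gap_run_len,
            )
        else:
            kept[species] = row
    return AlignedSet(gene=aligned.gene, rows=kept)


# ---------------------------------------------------------------------------
# Region extraction
# ---------------------------------------------------------------------------

def extract_region(cds: CodingSequence, region: Region | tuple) -> CodingSequence:
    """Codon-aligned sub-sequence for a region (0-based half-open codon
    coordinates).  The terminal stop codon is excluded from every region,
    including the whole-gene region."""
    if not isinstance(region, Region):
        region = Region(*region) if len(region) == 3 else Region("region", *region)
    sense = cds.sense_codons
    if region.end > len(sense):
        raise ValueError(
            f"region {region.name!r} [{region.start},{region.end}) out of bounds "
            f"for {len(sense)} sense codons of {cds.id!r}"
        )
    sub = "".join(sense[region.start : region.end])
    return replace(cds, id=f"{cds.id}:{region.name}", seq=sub)


def whole_region(cds: CodingSequence) -> Region:
    return Region(WHOLE_REGION_NAME, 0, len(cds.sense_codons))


# ---------------------------------------------------------------------------
# Partition / variant / alignment file formats
# ---------------------------------------------------------------------------

def read_partition(path) -> DomainPartition | dict[str, DomainPartition]:
    """Read a domain partition from YAML.

    Either a single partition (top-level ``regions:`` list of
    ``{name, start, end}`` mappings, applied to every gene) or a mapping
    gene -> region list.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if isinstance(data, Mapping) and "regions" in data:
        return DomainPartition.from_dict(data["regions"])
    if isinstance(data, Mapping):
        return {gene: DomainPartition.from_dict(entries) for gene, entries in data.items()}
    raise ValueError(f"unrecognized partition file layout in {path}")


def write_partition(partition: DomainPartition | Mapping[str, DomainPartition], path) -> None:
    def as_entries(p: DomainPartition):
        return [{"name": r.name, "start": r.start, "end": r.end} for r in p.regions]

    if isinstance(partition, DomainPartition):
        data = {"regions": as_entries(partition)}
    else:
        data = {gene: as_entries(p) for gene, p in partition.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_variants(path) -> list[VariantRecord]:
    """Read a 3-column TSV (position, ref, alt) with a header line."""
    out: list[VariantRecord] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            return out
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns")
            out.append(
                VariantRecord(int(parts[0]), parts[1].strip().upper(), parts[2].strip().upper())
            )
    return out


def write_variants(variants: Sequence[VariantRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tref\talt\n")
        for v in variants:
            fh.write(f"{v.cds_position}\t{v.ref}\t{v.alt}\n")


def read_alignment_fasta(path, gene: str = "") -> AlignedSet:
    """Read a gapped amino-acid alignment from FASTA (species = header)."""
    rows = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        rows[rec.description or rec.id] = str(rec.seq).upper()
    return AlignedSet(gene=gene, rows=rows)
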