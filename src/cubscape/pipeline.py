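"""Run the full analysis from a config: per-gene/per-species/per-region
codon-usage reports with cross-species summaries, and ΔLFE folding
profiles with intercepts, ramps and aggregates.

Outputs are tidy TSVs plus a JSON run manifest echoing the resolved
configuration.  Every stochastic step derives its seed deterministically
from the run seed and the (gene, species) pair, so reruns are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .codon_metrics import region_report, reports_to_frame
from .mfold import aggregate_profiles, delta_lfe_profile, get_backend
from .seqio import (
    DomainPartition,
    read_codon_table,
    read_fasta,
    read_partition,
    read_variants,
)
from .variants import summarize_mutations

logger = logging.getLogger(__name__)

DEFAULT_PARAMS: dict = {
    "nc_variant": "wright",
    "ecai_replicates": 500,
    "ecai_population": 0.90,
    "ecai_confidence": 0.90,
    "window": 40,
    "step": 10,
    "n_permutations": 20,
    "first_n": 10,
    "cub_cutoff": 35.0,
    "gap_cutoff": 60,
    "seed": 20231227,
    "summary": "mean",
    "folding_backend": "builtin",
}


@dataclass
class RunConfig:
    """Validated run configuration.

    ``genes`` maps gene name -> FASTA path (one record per species);
    ``codon_tables`` maps species -> Kazusa table path; ``partition`` is a
    YAML path (single partition or per-gene).  Unspecified parameters take
    the documented defaults.
    """

    genes: dict[str, str]
    codon_tables: dict[str, str]
    partition: str
    outdir: str
    variants: dict[str, str] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_PARAMS)
        merged.update(self.params or {})
        self.params = merged
        for label, path in [("partition", self.partition)] + [
            (f"genes[{g}]", p) for g, p in self.genes.items()
        ] + [(f"codon_tables[{s}]", p) for s, p in self.codon_tables.items()] + [
            (f"variants[{g}]", p) for g, p in self.variants.items()
        ]:
            if not Path(path).exists():
                raise FileNotFoundError(f"{label}: {path} does not exist")
        if self.params["window"] <= 0 or self.params["step"] <= 0:
            raise ValueError("window and step must be positive")
        if not 0 < self.params["ecai_population"] < 1:
            raise ValueError("ecai_population must be in (0,1)")
        if not 0 < self.params["ecai_confidence"] < 1:
            raise ValueError("ecai_confidence must be in (0,1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            genes={str(k): str(v) for k, v in data["genes"].items()},
            codon_tables={str(k): str(v) for k, v in data["codon_tables"].items()},
            partition=str(data["partition"]),
            outdir=str(data.get("outdir", "cubscape_out")),
            variants={str(k): str(v) for k, v in (data.get("variants") or {}).items()},
            params=dict(data.get("params") or {}),
        )

    def resolved(self) -> dict:
        return dataclasses.asdict(self)


def derive_seed(base_seed: int, *labels: str) -> int:
    """Stable per-(gene, species) seed below 2**31."""
    digest = hashlib.sha256(
        ":".join([str(base_seed), *labels]).encode()
    ).hexdigest()
    return int(digest[:8], 16) % (2**31)


def _load_inputs(config: RunConfig):
    tables = {
        sp: read_codon_table(path, species=sp)
        for sp, path in config.codon_tables.items()
    }
    partition = read_partition(config.partition)
    sequences = {gene: read_fasta(path) for gene, path in config.genes.items()}
    return tables, partition, sequences


def _partition_for(partition, gene: str) -> DomainPartition:
    if isinstance(partition, DomainPartition):
        return partition
    if gene in partition:
        return partition[gene]
    raise KeyError(f"no partition defined for gene {gene!r}")


def _write_manifest(config: RunConfig, outdir: Path, extra: Mapping) -> None:
    manifest = {"version": __version__, "config": config.resolved(), **extra}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def run_cub(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Per-species region reports and the cross-species summary per
    gene/region (unweighted mean by default, median by flag)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables, partition, sequences = _load_inputs(config)
    params = config.params

    reports = []
    counts: dict[str, int] = {}
    for gene, cds_list in sorted(sequences.items()):
        part = _partition_for(partition, gene)
        used = 0
        for cds in cds_list:
            if cds.species not in tables:
                logger.warning("run_cub: no codon table for %s; skipping %s", cds.species, cds.id)
                continue
            try:
                reports.extend(
                    region_report(
                        cds, part, tables[cds.species], params=params,
                        seed=derive_seed(params["seed"], "cub", gene, cds.species),
                    )
                )
                used += 1
            except (ValueError, KeyError) as exc:
                logger.warning("run_cub: skipping %s: %s", cds.id, exc)
        counts[gene] = used
        logger.info("run_cub: %s: %d species", gene, used)
        if used == 0:
            raise RuntimeError(f"gene {gene!r} has zero usable species")

    per_species = reports_to_frame(reports)
    numeric = [
        c for c in per_species.columns
        if c not in {"gene", "species", "region", "nc_variant", "cub_flag"}
    ]
    agg = "median" if params.get("summary") == "median" else "mean"
    summary = (
        per_species.groupby(["gene", "region"], sort=True)[numeric]
        .agg(agg)
        .reset_index()
    )
    per_species.to_csv(outdir / "cub_metrics.tsv", sep="\t", index=False)
    summary.to_csv(outdir / "cub_metrics_summary.tsv", sep="\t", index=False)
    _write_manifest(config, outdir, {"cub_species_counts": counts})
    return {"per_species": per_species, "summary": summary}


def run_lfe(config: RunConfig) -> dict[str, pd.DataFrame]:
    """ΔLFE profiles per species, intercept/ramp table, and per-gene
    cross-species aggregate profiles."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables, _, sequences = _load_inputs(config)
    params = config.params
    backend = get_backend(params.get("folding_backend", "builtin"))

    profile_rows, intercept_rows, aggregate_rows = [], [], []
    for gene, cds_list in sorted(sequences.items()):
        profiles = []
        for cds in cds_list:
            try:
                profile = delta_lfe_profile(
                    cds,
                    n_permutations=params["n_permutations"],
                    window=params["window"],
                    step=params["step"],
                    backend=backend,
                    seed=derive_seed(params["seed"], "lfe", gene, cds.species),
                )
            except ValueError as exc:
                logger.warning("run_lfe: skipping %s: %s", cds.id, exc)
                continue
            profiles.append(profile)
            profile_rows.append(profile.to_dataframe())
            intercept_rows.append(
                {
                    "gene": gene,
                    "species": cds.species,
                    "ramp_codons": profile.ramp_codons,
                    "x_intercepts_nt": ";".join(f"{x:.3f}" for x in profile.x_intercepts_nt),
                }
            )
        logger.info("run_lfe: %s: %d species", gene, len(profiles))
        if not profiles:
            raise RuntimeError(f"gene {gene!r} has zero usable species")
        aggregate_rows.append(aggregate_profiles(profiles).to_dataframe())

    profiles_df = pd.concat(profile_rows, ignore_index=True)
    intercepts_df = pd.DataFrame(intercept_rows)
    aggregates_df = pd.concat(aggregate_rows, ignore_index=True)
    profiles_df.to_csv(outdir / "lfe_profiles.tsv", sep="\t", index=False)
    intercepts_df.to_csv(outdir / "lfe_intercepts.tsv", sep="\t", index=False)
    aggregates_df.to_csv(outdir / "lfe_aggregates.tsv", sep="\t", index=False)
    _write_manifest(config, outdir, {"lfe_genes": sorted(sequences)})
    return {
        "profiles": profiles_df,
        "intercepts": intercepts_df,
        "aggregates": aggregates_df,
    }


def run_variants(cds_path, variants_path, out_path=None) -> dict:
    """Classify a variant TSV against a CDS FASTA and summarize abundances."""
    seqs = read_fasta(cds_path)
    if len(seqs) != 1:
        raise ValueError(f"expected exactly one CDS record in {cds_path}, got {len(seqs)}")
    variant_list = read_variants(variants_path)
    summary = summarize_mutations(seqs[0], variant_list).to_dict()
    if out_path is not None:
        with open(out_path, "w") as fh:
            json.dump(summary, fh, indent=2)
    return summary
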