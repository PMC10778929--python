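# cubscape

Intragenic codon-usage-bias (CUB) landscapes and local mRNA
folding-energy profiles for gene families.

Synonymous codons are not used interchangeably: within a gene, domains
can differ sharply in which synonymous codons they favor, and these
contrasts — rare-codon "ramps" near the start codon, GC3-elevated
domains, stronger- or weaker-than-expected mRNA secondary structure —
shape translation initiation and elongation, and can drive the
divergence of duplicated gene-family members. `cubscape` is a toolkit
for mapping those contrasts across the domains of a gene and across a
cohort of species' homologs. It was built with vertebrate gene families
of a few hundred codons across a few dozen species in mind (e.g. the
PP2A regulatory-subunit family), and ships a synthetic-data generator
that emulates exactly those study conditions so the entire pipeline is
testable without any database access.

## What it computes

For each domain (user-supplied codon coordinates), each species and the
whole gene:

* **Nc**, the effective number of codons (Wright's estimator). For each
  amino acid with degeneracy k ≥ 2 observed n ≥ 2 times, the codon
  homozygosity is F̂ = (n·Σp̂ᵢ² − 1)/(n − 1) over the synonymous
  proportions p̂ᵢ, and

  Nc = N₁ + N₂/F̄₂ + N₃/F̄₃ + N₄/F̄₄ + N₆/F̄₆,

  truncated at 61. Nc runs from 20 (one codon per amino acid, maximal
  bias) to 61 (uniform usage); Nc ≤ 35 flags a region as codon-usage
  biased. A pseudocounted variant (`ncw`) is selectable.
* **CAI**, the Codon Adaptation Index: the geometric mean of relative
  adaptiveness weights w_c = f_c / max(f) from a species codon usage
  table (ATG, TGG and stops excluded).
* **eCAI**, the CAI expected by chance for the same protein at the same
  GC content: an upper one-sided normal tolerance bound (default 90%
  population / 90% confidence) over 500 random synonymous sequences
  drawn from a GC-calibrated law. The percent difference between CAI
  and eCAI says whether a region is enriched for frequent (+) or rare
  (−) codons beyond composition effects.
* **GC3% and GC%**, with every domain value also normalized as the
  percent difference against its whole-gene value, so intergenic
  composition (isochores) does not masquerade as intragenic bias.
* **ΔLFE profiles**: sliding-window (40 nt, step 10) minimum folding
  energy of the native mRNA minus the mean over 20 whole-sequence
  synonymous-codon permutations. ΔLFE < 0 means stronger-than-predicted
  secondary structure. X-intercepts are interpolated and the 5′ ramp of
  weak structure is reported in codons. The default folding engine is a
  fast nested-structure dynamic program (GC/AU/GU pair energies,
  oracle-verified); a ViennaRNA backend is pluggable for kcal/mol.
* **Variant summaries**: synonymous / missense / nonsense classification
  of coding substitutions and the two abundance percentages
  (synonymous vs. all, synonymous vs. missense).

## Worked example

```python
from cubscape import nc, cai, ecai, gc3, percent_difference
from cubscape.seqio import Region, extract_region
from cubscape.synthetic_data import BiasProfile, RegionBias, generate_homolog_set

bias = BiasProfile(regions=[(Region("ramp", 0, 10), RegionBias("rare")),
                            (Region("body", 10, 200), RegionBias("frequent"))])
hs = generate_homolog_set(200, 1, bias=bias, seed=7, gene="demo")
cds, table = hs.sequences["sp01"], hs.tables["sp01"]
first10 = extract_region(cds, Region("first10", 0, 10))
print(f"whole-gene Nc      = {nc(cds):.2f}")
print(f"whole-gene CAI     = {cai(cds, table):.4f}")
print(f"whole-gene eCAI    = {ecai(cds, table, seed=1):.4f}")
print(f"CAI vs eCAI        = {percent_difference(cai(cds, table), ecai(cds, table, seed=1)):+.1f}%")
print(f"first-10-codon CAI = {cai(first10, table):.4f}")
print(f"whole-gene GC3     = {gc3(cds):.1f}%")
```

prints

```
whole-gene Nc      = 28.14
whole-gene CAI     = 0.5264
whole-gene eCAI    = 0.1312
CAI vs eCAI        = +301.2%
first-10-codon CAI = 0.0095
whole-gene GC3     = 53.5%
```

The gene was built with frequent codons everywhere except a rare-codon
first-ten ramp: the whole gene is strongly biased (Nc 28 ≤ 35) toward
frequent codons (CAI far above its chance expectation eCAI), while the
first ten codons have a CAI two orders of magnitude below the
whole-gene value — the ramp signature the pipeline is designed to pick
up.

The same analysis runs from the shell over a whole study:

```bash
cubscape synth --preset b56like --out study/          # 5 genes x 28 species
cubscape metrics --config study/config.yaml           # Nc/CAI/eCAI/GC3/GC tables
cubscape lfe     --config study/config.yaml           # ΔLFE profiles + ramps
cubscape variants --cds study/genes/B56a.fasta --variants study/B56a_variants.tsv
```

`metrics` writes `cub_metrics.tsv` (per gene/species/region) and
`cub_metrics_summary.tsv` (cross-species means); `lfe` writes
`lfe_profiles.tsv`, `lfe_intercepts.tsv` and `lfe_aggregates.tsv`, plus
a `manifest.json` echoing the resolved configuration.

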