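# Methods

This note documents the statistical models, parameter choices and
numerical conventions behind `cubscape`, and what the synthetic-data
generator does and does not emulate.

## Coordinates and alphabets

All region coordinates are 0-based, half-open, in codon units;
nucleotide coordinates appear only in the folding module (also 0-based,
half-open, measured from the CDS start). The internal alphabet is DNA;
RNA input is transcribed on entry and the folding engine transcribes
back to RNA. The terminal stop codon is stripped before every
codon-usage metric — they are defined over sense codons — but is kept
in the nucleotide sequence given to the folding profile, which covers
the full CDS. Codons containing N are excluded from all counts, and
any 40-nt window containing an N is reported as missing rather than
imputed.

## Effective number of codons (Nc)

The default estimator is Wright's. Per amino acid *a* with degeneracy
k ≥ 2 and count n ≥ 2, codon homozygosity is estimated as
F̂ = (n·Σp̂² − 1)/(n − 1); estimates ≤ 0 (a small-sample artifact) are
treated as missing rather than allowed to contribute negatively.
Class means F̄ₖ average the valid F̂ within each degeneracy class, and

Nc = N₁ + N₂/F̄₂ + N₃/F̄₃ + N₄/F̄₄ + N₆/F̄₆,

with Nₖ the number of degeneracy-k amino acids observed in the region
(N₁ counts Met and Trp, at most 2). The single three-fold class (Ile)
frequently has no valid F̂ in short regions; it then takes the standard
substitution F̄₃ = (F̄₂ + F̄₄)/2. If any other observed class is
unestimable, Nc is reported as missing with a warning rather than
guessed — short regions such as the first ten codons therefore often
carry no Nc, which the report format tolerates. Estimates above the
theoretical maximum (possible because the bias correction can push
F̂ below 1/k) are truncated to 61 and flagged. The `ncw` variant
replaces the bias-corrected F̂ by the plain sum of squared pseudocounted
proportions pᵢ = (nᵢ + 1)/(n + k) over the full family; it exists for
comparability with the CAIcal service and is selectable per run
(`nc_variant: ncw`), with Wright remaining the verifiable default.

A region is flagged as possessing codon usage bias when Nc ≤ 35
(`cub_cutoff`, configurable).

## CAI and its chance expectation (eCAI)

Relative adaptiveness weights are w_c = f_c / max(f) within each
synonymous family, from the species' codon usage table (frequencies
per thousand, Kazusa text format). Zero-frequency codons receive a
pseudo-frequency — 0.5 occurrences on the table's count scale when
counts are known, otherwise half the smallest positive entry — so every
weight is strictly positive and CAI is always defined. CAI is the
geometric mean of w over the region's codons, excluding ATG, TGG and
stops (no synonymous choice exists there); a region with no
contributing codons is an error, and eCAI inherits that error in the
no-synonymous-freedom case since every replicate would equal the
native sequence.

eCAI asks: what CAI would chance alone produce for this protein at
this GC content? Replicate synonymous sequences preserve the amino
acid sequence; each residue's codon is drawn from its family with
probability ∝ θ^g(c), where g(c) is the codon's G+C count and θ is
calibrated by bisection on log θ (tolerance 10⁻⁶ on the GC fraction)
so the expected replicate GC equals the query region's GC. When the
query GC lies outside the synonymously achievable range, θ clamps to
the bracket end with a warning. The reported eCAI is the one-sided
upper normal tolerance bound m + k·s over 500 replicate CAI values,
with the k-factor from the noncentral-t quantile at 90% population /
90% confidence (the defaults); with n = 500 the factor is stable to
four decimals. The bound is capped at 1 to stay on the CAI scale.
This GC-tilted per-residue law is this package's interpretation of
"random synonymous sequences of similar GC content"; it is not a
bit-for-bit reimplementation of any external server's sampler. Its
internal calibration is tested: a native sequence drawn from the same
law sits inside the replicate CAI distribution.

## GC3, GC and normalization

GC3% is the percentage of codons (stops excluded, Met/Trp included)
with G or C at the third position; GC% is over all region nucleotides.
Every domain metric is additionally normalized as the percent
difference 100·(domain − whole)/whole against the whole-gene value, so
regional composition differences are read against the gene's own
background rather than absolute scales. The same percent difference
compares CAI against eCAI (positive: frequent-codon enrichment;
negative: rare-codon enrichment). Percentages are kept at full
precision internally and rounded only at presentation.

## ΔLFE profiles

Local folding energy is computed over 40-nt windows at a 10-nt step —
all full windows, no partial tails, each profile value anchored at its
window's start coordinate. The null model is the whole-sequence
synonymous permutation: codons are shuffled uniformly among positions
encoding the same amino acid, exactly preserving the protein, the
codon multiset and hence the nucleotide content. ΔLFE(w) = native
LFE(w) − mean over 20 permutations of LFE at the same coordinates;
negative values mean stronger-than-predicted structure. Permuting the
whole sequence (rather than within windows) keeps long-range codon
placement in the null, matching the profile's purpose of locating
where the *native* arrangement is atypical.

The built-in folding engine is a nested-structure dynamic program:
allowed pairs GC (−3), AU (−2), GU (−1), minimum hairpin loop of 3
unpaired bases, no pseudoknots, with traceback available from the
pure-Python reference implementation. Its energies are in arbitrary
units — the sign and zero structure of ΔLFE are the portable
quantities, and those are what ramps and intercepts are derived from.
The DP is verified against exhaustive enumeration of all nested
structures up to length 18 and runs through a numba-compiled batch
path for profile-scale workloads. A ViennaRNA backend satisfies the
same contract for users wanting thermodynamic kcal/mol energies; the
two backends agree on sign structure but not absolute values, so
absolute LFE is backend-dependent by design.

X-intercepts interpolate linearly between consecutive window-start
anchored ΔLFE values where the sign changes; exact zeros are reported
at their window start. The ramp length is the 5′ prefix of
weaker-than-predicted structure: floor(first positive-to-negative
crossing / 3) codons, 0 when the profile opens at or below zero, and
the full profile length in codons when ΔLFE never goes negative.
Cross-species aggregation takes the unweighted arithmetic mean per
window start over the species that have a valid window there
(medians by flag); positions nobody covers are absent, and missing
windows are excluded rather than imputed.

## Variant classification

Substitutions are classified by translating the affected codon before
and after under the standard genetic code: synonymous (same amino
acid, including stop→stop), missense, nonsense (sense→stop), stop_loss
(stop→sense). Only single-nucleotide substitutions are accepted —
the abundance arithmetic (synonymous vs. all, synonymous vs. missense)
concerns substitutions — and indels are rejected with a message. The
classifier is checked exhaustively (64 codons × 3 positions × 3
alternates) against an independently hand-typed genetic code.

## Sequence curation

Alignment rows (gapped amino-acid strings) containing a contiguous gap
run of 60 or more residues are excluded, with the removal logged per
species; the filter is idempotent and the threshold configurable
(`gap_cutoff`). Alignments are consumed, never computed. Domain
boundaries cannot be inferred from sequence and are explicit inputs
(YAML, per-gene or shared); the packaged default partition splits a
gene 20% / 60% / 20% into N-terminus, core and C-terminus, which is a
fixture convention, not a biological claim.

## Synthetic data: what it emulates, and what it does not

The generator exists so every stage of the pipeline can be exercised
on data with known structure. It emulates: species-specific codon
usage tables (per-family Dirichlet frequencies, concentration
1/(1+skew), default skew 2.0 — strongly but not degenerately biased
families); multi-species homolog sets sharing one protein exactly;
per-region codon-sampling contrasts ("frequent": argmax-weight codon
with probability 0.9, others uniform; "rare": probability ∝ 1/w with
w floored at 0.05; "uniform"; "gc3_tilted": third-position G/C tilt
with θ calibrated by bisection to a target GC3); designed 5′ hairpins
(G/C-only stems around an A loop, placed on codon boundaries, identical
across species, stop-free by construction) whose stems synonymous
shuffles disrupt; and variant lists rejection-sampled to exact class
quotas. The study-scale preset uses 5 genes × 28 pseudo-species at
500 codons — the cohort geometry and gene size of a typical vertebrate
gene-family analysis — with one gene carrying a rare-codon first-ten
ramp, a GC3-elevated N-terminal domain (target 0.80) and a hairpin at
nt 30; one a frequent-codon N-terminus; one a GC3-elevated N-terminus
(target 0.85); and two unbiased.

It deliberately does **not** emulate: amino-acid divergence between
species (homologs are synonymous-only variants of one protein),
phylogenetic correlation among species (tables and codon draws are
independent), splice-variant structure, thermodynamically realistic
folding energies, or real codon-frequency vectors of named species.
Passing tests therefore demonstrate that the estimators recover known
synonymous-level structure under idealized sampling — not that any
particular biological dataset will show such structure, nor that
effect sizes transfer to real genes.

## Determinism and seeds

Every stochastic operation takes an explicit seed; the pipeline default
is 20231227. Per-(gene, species) seeds derive from the run seed via
SHA-256, so outputs are byte-identical across reruns and independent of
iteration order. Test problem sizes (e.g. 120–300-codon genes for
calibration checks, 100-seed recovery sweeps, one full-scale 5 × 28 ×
500-codon end-to-end run) were chosen to make the suite a routine
desk-check while keeping every statistical assertion at conventional
2-standard-error or ≥95%-of-seeds strength.

## Known limitations

* Nc is undefined (reported missing) for regions where an observed
  degeneracy class other than Ile's has no family with n ≥ 2 — common
  below ~30 codons; the first-ten analysis relies on CAI, not Nc.
* The exact Ncw formula of the CAIcal service is not published in
  detail; the `ncw` option implements the standard pseudocounted
  homozygosity and may differ from that service in edge cases.
* eCAI is a tolerance bound, not a mean: it is by construction above
  the replicate mean, and comparisons against it are conservative.
* The built-in folding model has no stacking, dangles or temperature
  dependence; ramps/intercepts are robust to this, absolute energies
  are not.
* Aggregate profiles align species from the CDS start; genes with
  length variation have decreasing support toward the 3′ end, visible
  in `n_species`.
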