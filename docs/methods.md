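# Methods

This note documents the models behind `padscan`, the parameters that
matter, the synthetic data the test suite runs on, and the numerical
and design choices made where the design was genuinely open.

## The problem

In plants, as in animals, chromatin at the nuclear periphery is
transcriptionally repressed, and pull-down experiments with a tagged
nuclear-pore-basket protein recover the DNA in contact with it. The
pipeline turns such data into *periphery-enriched domains* — broad
(multi-kilobase) intervals enriched in both replicates of the pull-down
relative to an IgG control — and then asks how those domains relate to
Hi-C compartments, gene content, chromatin loops, expression and DNA
methylation pathways.

## Signal model and island calling

Fragments are assigned to fixed windows by midpoint (a fragment
contributes to exactly one window, so bin totals are conserved; at the
1-kb calling resolution with ~200-bp fragments the difference from
proportional assignment is negligible). "Normalized coverage" is
fragments-per-million; the displayed signal is
`log2((GFP + c) / (IgG + c))` with pseudocount `c = 0.5` per-million
units, which bounds log-ratios on sparse bins and maps double-empty
bins to exactly 0.

The caller follows the island framework for broad marks:

1. background rate `λ_bg` = genome-mean fragment count per W-bp window
   (floored at `lambda_floor = 1e-3` to keep Poisson tails defined on
   pathological inputs);
2. a window is eligible iff `P(X ≥ count | λ_bg) < p_elig` with
   `p_elig = 0.2` (the conventional island-caller default; exposed in
   `IslandParams`);
3. eligible windows at most G bp apart (counting the ineligible windows
   between them) chain into one island spanning first to last eligible
   window;
4. the island p-value is the Poisson upper tail of its aggregate count
   with mean `max(depth-scaled control aggregate, λ_bg × windows)`;
   control depth scaling is internal (chip total / control total), so
   calls are invariant under uniform rescaling of control depth, and an
   empty control falls back to the background-only test with a warning;
5. Benjamini–Hochberg across islands; keep q < FDR.

Defaults are W = 1000 bp, G = 3000 bp, FDR = 0.01 — the standard
parameterisation for this assay. Replicate calls are intersected at bp
level ("shared between replicates" read as set intersection);
intersection is commutative, associative and idempotent. The gene
enrichment rule is strict: a gene (or TE) is enriched iff the union of
domain overlap exceeds 80% of its span — a fraction of exactly 0.8 does
not qualify. The pericentromere distance filter is inclusive: an
interval exactly 1 Mb away is kept.

## Hi-C compartments

Per-arm analysis only: bins fully left/right of the pericentromere form
the left/right arm; arms under 10 bins are skipped. The arm submatrix
is first distance-normalised (each diagonal divided by its mean,
"observed/expected"). This step is essential: on a matrix with
realistic distance decay, row ranks are dominated by proximity to the
diagonal and the leading principal component tracks position along the
arm rather than compartment membership (recovery at chance level in
simulation). Observed/expected is not matrix balancing — no iterative
correction of bin visibilities is performed; the input is assumed
already normalized.

The Spearman correlation of rows i and j excludes the two diagonal
positions of the pair (self-contact bins) and masked bins; zero-variance
rows are masked. PCA column-centres the correlation matrix and takes
the projection onto the leading right singular vector (numpy SVD; the
eigen-equation residual is checked against 1e-8). The PC1 sign is
intrinsically arbitrary, so it is fixed by requiring a non-negative
Spearman correlation with the periphery log2 signal at the same
binning; oriented PC1 > 0 is labelled peripheral-like. A constant
signal leaves the orientation at + with a warning.

Telomere profiles intentionally use the *raw* (non-O/E) Spearman
correlation between each distal bin and the terminal bin: the gradual
distance-driven decline is the object of interest, and local dips below
a running-median trend (half-width k = 10 bins, depth δ = 0.1, both
configurable — the criterion is descriptive, not inferential) mark
regions whose 3D contact with the telomere is locally depleted.

## Permutation nulls

The null for domain-vs-annotation statistics preserves the genomic
arrangement of the domains: every domain is translated by a magnitude
drawn from {50 kb, 100 kb} with an independent random sign, re-drawn
per domain per round. Domains pushed past a chromosome end are
reflected back about the edge (preserving the length multiset); the
rare interval that straddles the edge after shifting slides flush to
it instead. Overlaps created by shifting are left as-is. Empirical
p-values are `(1 + #{null ≥ obs}) / (n_perm + 1)`, never zero; the
two-sided p doubles the smaller tail, capped at 1. The default
`n_perm = 999` is configurable (the calibration suite uses 199 rounds
across 200 replicate simulations, a problem size chosen to keep the
whole suite fast while still resolving p at 0.005 granularity).
Calibration holds: with domains placed independently of annotations the
p distribution is uniform within KS distance 0.1.

Loop anchors belong to a domain when strictly more than 50% of the
anchor's bp fall inside that single domain; loops are intra (both
anchors, same domain), across (exactly one anchor in a domain, or two
different domains) or outside, and trans-chromosomal loops are excluded
with a count. Expression comparisons use the Mann–Whitney U test
(exact null when the pooled sample is ≤12 and untied, else the
tie-corrected normal approximation with continuity correction).
Expression-matched control sets bin the enriched genes' expression into
20 quantile bins and sample non-enriched genes proportionally, without
replacement per bin.

## Metaprofiles

Boundary profiles orient each domain boundary so that positive
positions point into the domain; boundaries whose ±flank (default
20 kb) exits the chromosome are dropped. For region-type (binary)
marks, the per-position value is the fraction of boundaries whose
100-bp window overlaps a mark region; for numeric 100-bp tracks, the
mean window value.

Scaled TE-body metaplots expand each element's 100-bp window values to
bp resolution and average them within S = 40 equal body bins, so the
boundaries of all elements align and every element — long or short —
contributes to every bin (a midpoint-to-bin assignment would leave most
bins of a 1-kb element empty). Minus-strand elements are reversed.
Flanking regions are body-external and excluded by default. TE location
grouping reuses the strict >80% rule for consistency with gene
enrichment.

## The synthetic data

The generator produces the statistical structure the analysis assumes,
at desk scale, with all randomness flowing from one root seed through
named substreams (component × sample × replicate), so a dataset is a
pure function of (config, seed).

- **Genome**: 5 chromosomes × 3 Mb (multi-chromosome logic at <1% of a
  real plant genome); pericentromere = central 20% of each chromosome,
  centromere = its central third.
- **True domains**: placed on arms only (the pericentromere is
  implicitly peripheral); log-normal lengths with median 9 kb and
  log-sd 0.6, accumulated per arm until the 15%-of-arm coverage target
  is met as closely as possible (realized coverage within ±1 point);
  spacing ≥ 2×G = 6 kb between domains *and* against arm ends, so
  called islands never bridge across a gap or into the pericentromeric
  signal block.
- **Fragments**: 2×10⁵ per sample, 200 bp, drawn from a
  piecewise-constant intensity — uniform for IgG; baseline × 3 inside
  true domains and pericentromeres for GFP. The 3-fold enrichment is a
  free parameter of the simulator (no quantitative pull-down fold is
  established for this assay), chosen as a moderate, realistic
  signal-to-background for a broad-domain experiment.
- **Annotations**: protein-coding genes uniform over arms (1 per 6 kb,
  2-kb median lengths); enriched ones (span >80% in domains) draw
  expression from a lower log-mean component. TE genes at 1 per 50 kb
  outside and 4× that inside domains, placed by per-segment rejection
  sampling so the realized density ratio matches the configured one
  (post-hoc overlap thinning would depress it); sparse pseudogenes.
  A TE inside a domain is CMT2-dependent with probability 0.8, else
  RdDM-dependent (and vice versa outside) — a preference, not a
  partition.
- **Hi-C**: 20-kb bins; contact(i,j) = (1+|i−j|)^(−1) ×
  (1 + 0.6 if bins share the true compartment label) × symmetric
  log-normal noise (sd 0.1). A bin is truly peripheral when ≥50% of it
  overlaps domains or pericentromere.
- **Methylation**: per-100-bp Beta-distributed ratios (concentration
  30) around context baselines CG 0.85/0.75, CHG 0.60/0.45,
  CHH 0.35/0.22 for peripheral/interior TEs (CG > CHG > CHH, higher at
  the periphery). Genotypes: met1-like zeroes CG; cmt3-like multiplies
  CHG by 0.3; cmt2-like multiplies CHH by 0.2 on CMT2-dependent TEs
  only; drm12-like does the same on RdDM-dependent TEs.
- **Loops**: anchors of 4 kb with a configured intra/across/outside
  mix; **sequence** (optional) is i.i.d. nucleotides with configurable
  GC inside/outside domains.

What the generator does *not* emulate — and what passing tests
therefore do not show about real data: mappability and copy-number
artifacts, fragment-length and GC bias, restriction-site spacing,
chromatin-state autocorrelation in the background, partial methylation
epiallele structure, or cell-type mixtures within a tissue. Recovery
results certify the correctness of the computational pipeline under its
own model assumptions, not the biological effect sizes.

## Numerical choices and degenerate inputs

Poisson tails via `scipy.stats.poisson.sf` (checked against direct pmf
summation to 1e-9 in the test suite); BH q-values enforce monotonicity
from the largest rank down. Dense matrices asymmetric beyond 1e-9 are
symmetrised by averaging with a warning; NaN cells are carried as
masked bins and excluded from correlations, and bins left unmasked
overall but undefined against some partner are imputed with the column
mean before the SVD. Zero-length queries, empty groups, unknown
genotypes, non-square matrices and windows misaligned to a track raise
immediately rather than propagating silently. GFF3 is converted from
1-based closed to the internal 0-based half-open convention on read;
unknown biotypes map to protein_coding with a logged warning; strand is
carried but ignored by all overlap computations.

## Problem sizes

Defaults are deliberately desk-scale: the full recovery run (simulate,
bin, call, intersect, compare) completes in well under two minutes on
one CPU, the whole test suite in about a minute. The acceptance script
uses the default configuration unchanged, with the caller's seed as the
simulation root seed.

## Known limitations

- The caller's island score (summed −log10 window p) is reported but
  not used for ranking beyond BH on island p-values; no sub-window
  boundary refinement is attempted, so domain edges are quantised to W.
- Compartment PCA column-centres the correlation matrix (centring
  rows, or both, would change scores only marginally for symmetric
  inputs; one convention is fixed and documented).
- Valley/peak colocalization on telomere profiles is provided as
  machinery only; no significance is attached.
- The pipeline consumes aligned fragments, not reads: alignment,
  duplicate marking and mapping-quality filtering are upstream of this
  package.
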