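# padscan

Analysis toolkit for mapping chromatin domains tethered to the nuclear
periphery from pull-down sequencing data (RE-ChIP-style experiments in
which a GFP-tagged nuclear-pore protein is the bait and IgG the
non-specific control), together with the downstream analyses that
characterise those domains: Hi-C compartment comparison, gene/TE
enrichment against coordinate-shift permutation nulls, and DNA
methylation metaprofiles over transposable elements.

It is aimed at plant epigenomics groups who have per-replicate aligned
fragment intervals (BED), gene/TE annotation (GFF3), normalized 20-kb
Hi-C matrices (dense TSV), per-context bisulfite tracks (bedGraph) and
chromatin loops (BEDPE), and want a reproducible, tested pipeline from
coverage tracks to called periphery-enriched domains and their genomic
correlates. A first-class synthetic-data generator emulates all of these
inputs with known ground truth, so every stage is testable without any
download.

## What it computes

**Signal tracks.** Fragments are binned by midpoint into fixed windows
(50 kb for chromosome overviews, 20 kb for compartment comparison, 1 kb
for calling), depth-normalised to fragments-per-million, and summarised
as `log2((GFP + c) / (IgG + c))` with pseudocount `c = 0.5`.

**Broad-domain calling.** A SICER-style island caller on W = 1000 bp
windows: a window is *eligible* when the one-sided Poisson upper-tail
probability of its fragment count under the genome-wide background
`λ_bg` is below 0.2; eligible windows separated by at most G = 3000 bp
of ineligible windows chain into islands; each island's aggregate count
is tested against `max(depth-scaled IgG aggregate, λ_bg · windows)` and
islands with Benjamini–Hochberg q < 0.01 are kept. Domains are the
bp-level intersection of the two replicate calls; a gene counts as
enriched when strictly more than 80% of its transcribed region lies in
domains, and analyses of arm features can exclude everything within
1 Mb of pericentromeric heterochromatin.

**Hi-C compartments.** Per chromosome arm, the contact matrix is
distance-normalised (observed/expected), converted to a Spearman
correlation matrix, and the first principal component of the
column-centred correlation matrix is extracted; its sign is oriented so
PC1 correlates positively with the periphery signal, and bins with
oriented PC1 > 0 are labelled peripheral-like (the repressed, B-type
compartment). A telomere-anchored correlation profile with
running-median valley detection covers the distal-arm analysis.

**Permutation enrichment.** The null preserves the genomic arrangement
of called domains by translating each domain ±50 kb or ±100 kb (drawn
independently per domain per round); empirical p-values use the +1
correction. The same machinery classifies chromatin loops as
intra-domain / across-boundary / outside, compares expression
(Mann–Whitney U), and draws expression-matched control gene sets by
quantile binning.

**Metaprofiles.** Marks and GC content around domain boundaries in
oriented 100-bp windows (positive positions point into the domain), and
length-normalised CG/CHG/CHH metaplots over TE bodies, with TEs grouped
peripheral vs non-peripheral by the same strict >80% rule and contrasted
across methyltransferase-mutant genotypes (CMT2-like vs RdDM-like CHH
pathways).

## Worked example

The headline analysis — simulate the default dataset, call domains in
both replicates, intersect, clip to arms, and compare with the ground
truth:

```python
from padscan.simulate import SimulationConfig
from padscan.pipeline import run_domain_recovery

result = run_domain_recovery(SimulationConfig(seed=7))
print(f"called arm domains : {len(result['called_arms'].intervals)}")
print(f"genome coverage    : {result['genome_coverage_pct']:.1f} %")
print(f"median length      : {result['median_length_kb']:.1f} kb")
print(f"bp-Jaccard vs truth: {result['jaccard']:.3f}")
```

prints

```
called arm domains : 165
genome coverage    : 11.7 %
median length      : 9.0 kb
bp-Jaccard vs truth: 0.922
```

The simulated truth places domains over 15% of the chromosome arms
(≈12% of the genome) with 9-kb median lengths; the called,
replicate-intersected domains recover that coverage and size range and
overlap the truth at bp-Jaccard 0.92 — the calling pipeline neither
inflates nor erodes the domains it is given.

The same analysis from the shell:

```bash
padscan simulate --seed 7 --outdir sim/
padscan call-domains --gfp sim/fragments_GFP_rep1.bed --igg sim/fragments_IgG_rep1.bed \
    --layout sim/layout.tsv --out rep1.bed
padscan call-domains --gfp sim/fragments_GFP_rep2.bed --igg sim/fragments_IgG_rep2.bed \
    --layout sim/layout.tsv --out rep2.bed
padscan intersect rep1.bed rep2.bed --out domains.bed
padscan summarize --domains domains.bed --layout sim/layout.tsv --arms-only
```

`padscan run --config cfg.yaml --seed 7 --outdir out/` executes the full
pipeline (simulate → tracks → domains → compartments → enrichment →
metaprofiles) from one config file and writes a manifest of outputs.

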