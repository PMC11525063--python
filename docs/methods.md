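# Methods

This note documents the statistical models, numerical choices and known
limitations behind `grmkit`, in the order of the pipeline stages.

## Differential testing (expression and accessibility)

Counts are modelled only implicitly: the contrast operates on log2-CPM with a
0.5-count offset, `log2((count + 0.5) * 1e6 / (library_size * factor))`,
where the per-sample factor comes from TMM normalisation. The identical code
path serves gene counts (differential expression) and ROC counts
(differential accessibility); only the feature ids and the fold-change
threshold differ (1.0 for expression, 0.68 for accessibility, the latter
being the fold-change that corresponds to q ≤ 0.05 in the calibrated
accessibility contrast and therefore treated as a constant parameter).

**Low-signal filter.** A feature is kept when at most 2 libraries have
CPM < 1. Both bounds are parameters; the defaults mirror standard practice
for three-replicate designs.

**TMM.** The reference sample is the one whose upper-quartile count fraction
is closest to the mean upper-quartile. M (log2 fraction ratio) and A (mean
log2 abundance) values are computed over features positive in both sample
and reference; the trim keeps M within its [0.30, 0.70] and A within its
[0.05, 0.95] empirical quantiles (quantile masks rather than rank-count
arithmetic — a deliberate, documented choice that keeps the trim exactly
reproducible); the factor is 2 to the inverse-variance weighted mean of the
retained M values, with the standard delta-method weights, and factors are
rescaled to geometric mean 1. Note the scale convention: factors act
multiplicatively on library sizes, so rescaling a whole library leaves its
factor invariant while the *effective* library size scales proportionally.

**Test statistic.** The default is a moderated t: per-feature pooled
variances (df = n₁ + n₂ − 2) are shrunk toward a scaled-inverse-chi-square
prior fitted by matching the moments of log s² (the classic empirical-Bayes
recipe; the prior df solves a trigamma equation by Newton iteration, and a
non-positive moment estimate collapses all variances to their common mean).
The p-value uses a t distribution with prior + residual degrees of freedom.
At two or three replicates per group a raw Welch t is too noisy to rank
features — its recovery of strong planted effects plateaus around 80–85%
under FDR control purely because of variance-estimate sampling error — so
moderation is the default; `statistic="welch"` remains available as the
unmoderated reference. The shrinkage implementation is cross-checked in the
test suite against Bioconductor limma's `squeezeVar` on the same inputs.

**Signature.** |log2FC| ≥ threshold is closed (a gene exactly at the
threshold is included); FDR < α is strict. Up and down sets are disjoint by
construction.

## Chromatin landscape

Each ROC is assigned to the gene whose TSS (strand-aware 5′ end of the span;
one TSS per gene) minimises the distance to the ROC midpoint,
floor((start+end)/2), on the same chromosome; exact ties go to the
lexicographically smaller gene id, and ROC on chromosomes without gene
models are dropped with a logged count. Midpoint distance was chosen over
edge distance because it is symmetric and matches common peak annotators;
the distance is reported signed and strand-oriented. Non-significant ROC
remain in every gene's landscape — only the open/closed/unchanged label
depends on the (q, fold-change) gates.

The accessibility-vs-expression relation is summarised by a robust line fit:
IRLS with Tukey bisquare loss (tuning constant 4.685, 95% Gaussian
efficiency), initialised from least squares with MAD residual scale
(delegated to statsmodels RLM). Because robust R² has several variants, the
reported diagnostic is defined explicitly as 1 − Σw(y−ŷ)²/Σw(y−ȳ_w)² with
the converged weights w and the weighted mean ȳ_w, clipped to [0, 1]. A
perfect linear relation makes the MAD scale zero; that case short-circuits
to the ordinary least-squares line with R² = 1.

## Binding matrix

"Bound" means the footprint's p-value in the chosen condition is strictly
below 0.01 (the contrast lineage by default; when a p-value is absent a
right-tail plug-in empirical p, (1 + #null ≥ score)/(1 + #null), can be
computed from a supplied null score sample). Differential binding is
score_b − score_a. Cells aggregate to TF level — one column per TF, the mean
over that TF's bound sites per gene — and a missing (gene, TF) pair is 0,
not NA: k-means needs complete data and zero is the natural neutral value
for a differential score ("no evidence of differential occupancy").
Footprints at identical coordinates under several TF names contribute to
every named TF's cell; the duplicate share of any footprint subset (the
fraction of records whose exact coordinates are shared with a record of a
different TF) is reported alongside each module because high duplication
flags motif-family ambiguity rather than independent binding evidence.

## Module discovery

Rows are z-scored with the population standard deviation (constant rows map
to zeros) so that genes contribute comparable profiles regardless of their
absolute binding level. Two independent k-means runs — one over genes, one
over TF columns of the same scaled matrix — implement the double clustering;
no iterative co-clustering couples them. k-means uses Euclidean distance,
k-means++ initialisation, 10 restarts, a 300-iteration cap and tolerance
1e-6, all seeded; k is selected per axis as the silhouette-maximising value
over 2..10 (ties to the smaller k), with the inertia (elbow) curve returned
for inspection and a best silhouette ≤ 0.3 flagged as weak structure.

Density is always computed on the **unscaled** matrix: the sum of a module's
cells divided by its surface area |genes| × |TFs|. Candidate modules (all
gene-cluster × TF-cluster pairings) are ranked by |density| within an
expression direction; single-TF clusters are excluded by default (a lone
insulator-like TF can dominate density without constituting a module), and
the top 3 per direction are reported. Clustering runs separately for the up-
and down-regulated signature halves.

## Networks

All network constructs run at gene resolution: a TF "binds" a gene when any
of its bound footprints is annotated to that gene. A regulon is the edge set
(TF, target) with support counts and mean differential binding; a
co-regulation subnetwork around a focal TF is a partner TF whose own gene
locus the focal TF binds and whose regulon shares ≥ 1 target with the focal
regulon (bound partners without shared targets are reported separately); a
feed-forward loop is a triple (focal, intermediate, target) with focal →
intermediate-gene, intermediate → target and focal → target all bound.
Graphs are exported as edge TSV / GraphML; layout is left to external tools.

## Variant burden

Filters: depth ≥ 30 (inclusive), consequence not in the excluded set
(synonymous by default), AF_NFE < 0.01 (strict); a missing AF_NFE is kept as
rare — in gnomAD-style annotation an absent frequency usually means the
allele was unobserved — with `drop_missing_af` to invert. A gene's locus is
the interval union of its span and its annotated ROC (a `--genes-only`
style restriction is a parameter choice away). Burden per individual and
gene set: fraction of set genes with ≥ 1 carried passing SNV in their locus,
and carried passing SNVs per 100 kb of total locus length (a variant inside
two genes' loci counts once per locus; the denominator is the per-set locus
length). Cohort contrasts use the two-sided Mann–Whitney U (independent
cohorts) or Wilcoxon signed-rank (paired within-cohort set contrasts), with
BH correction across the declared family; fully tied inputs return p = 1.
Patient stratification z-scores the burden columns (constant columns are
dropped), applies Ward linkage on Euclidean distance, cuts at the
silhouette-best k in 2..8 unless k is given, and reports the two-cluster cut
as the top-level split.

## Synthetic data: what it emulates, and what it does not

The generator plants known structure in every layer so recovery is
measurable:

- **Expression** — negative-binomial counts (variance μ + φμ²) with
  log-normal baselines (median ≈ 200 counts, log-sd 1.0 — a realistic
  dynamic range for filtered bulk RNA-seq), three replicates per group,
  library sizes varying ≤ 2×, ~10% planted DE genes at |log2FC| = 3 with NB
  dispersion φ = 0.05.
- **Landscape** — ~4 ROC per gene placed within ±50 kb of the TSS on one
  synthetic chromosome of tiled, non-overlapping genes; a few percent of ROC
  carry a planted ±1.5 accessibility log2FC; planted module shifts are keyed
  on the *actual* nearest-TSS annotation of each ROC so downstream recovery
  is self-consistent.
- **Binding** — footprint score differences are drawn directly
  (N(±δ, sd) inside planted gene × TF blocks, N(0, sd) elsewhere; δ = 1.0,
  sd = 0.2 by default); 14.8% of footprints end up duplicated under a second
  TF name at identical coordinates, matching the observed motif-ambiguity
  rate. Footprint scores are generated, not derived from per-base cut-site
  signal: the pipeline's contract starts at scores. A matrix-level
  generator (`simulate_binding_matrix`) plants the same block structure
  directly in the gene × TF matrix for fast clustering studies.
- **Cohorts** — per-individual, per-locus Poisson SNV counts at 2 SNV/100 kb
  baseline, multiplied by ρ = 3 for module genes in cases (35 vs 35
  individuals); AF_NFE is a mixture with mass below and above 0.01 plus a
  5% missing fraction, 30% of variants are synonymous, and depth is a
  discretised normal around 40×, so each downstream filter removes real
  records.

Deliberately not emulated: genome sequence content, linkage and genotype
correlation between variants (each synthetic SNV has one carrier), indels
and structural variants, multi-transcript genes, overlapping genes, and
chromatin contact structure. Passing tests therefore demonstrate that the
*procedures* recover planted statistical structure at realistic effect
sizes, not that real sequencing data would yield any particular module.

## Problem sizes and determinism

All stochastic stages take explicit seeds (numpy Generator); identical
configurations produce byte-identical output files. The test suite and the
acceptance script run at desk scale by design: expression studies use
1,000–2,000 genes, clustering studies 200 × 40 matrices over 50 seeds, and
cohort studies ~300-gene universes with 50-gene modules — sizes at which
every planted-recovery property is already decisively measurable.

## Known limitations

- The moderated t assumes a common variance prior across features; strong
  mean-variance trends (which voom models with precision weights) are only
  partially absorbed.
- Silhouette-based k selection favours merging under weak separation; the
  elbow curve and weak-structure flag are reported so users can override k.
- Nearest-TSS annotation is a heuristic for regulatory assignment; enhancers
  acting over longer ranges or across genes are mis-assigned by
  construction.
- Burden metrics treat SNVs as exchangeable counts; no pathogenicity
  weighting or zygosity modelling is attempted.
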