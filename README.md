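# grmkit

Tools for deriving **Gene Regulatory Modules (GRMs)** from paired expression
and chromatin-accessibility contrasts between two cell lineages, and for
scoring the rare-variant burden of the resulting gene sets in patient
cohorts.

The motivating setting is bulk RNA-seq plus ATAC-seq of two closely related
T-cell lineages (e.g. thymic regulatory vs conventional CD4 single-positive
thymocytes). Transcription-factor (TF) footprints inside regions of open
chromatin (ROC) carry per-condition occupancy scores; the *differential
binding* of a TF at a site — its occupancy score in one lineage minus the
other — is treated as a direct, quantitative readout of lineage-specific TF
activity. `grmkit` turns those site-level scores into modules of co-regulated
genes and co-acting TFs, and then asks whether the module genes are
mutational hotspots in whole-genome-sequenced cohorts.

## The method

1. **Signature** — a two-group contrast on counts (CPM conversion, a
   low-signal filter keeping features with < 1 CPM in at most 2 libraries,
   TMM scaling, a variance-moderated t statistic on log2-CPM, and
   Benjamini–Hochberg FDR) defines the differentially expressed genes
   (|log2FC| ≥ 1, FDR < 0.05). The identical machinery applied to ROC counts
   classifies accessibility as open / closed / unchanged (q ≤ 0.05 with
   |log2FC| ≥ 0.68). A robust MM-type line fit of mean accessibility change
   on expression change quantifies how far accessibility explains expression.
2. **Binding matrix** — each ROC is annotated to its nearest transcription
   start site; footprints bound in the contrast lineage (p < 0.01) are
   aggregated into a genes × TFs matrix whose cell (g, t) is the mean
   differential binding of all bound sites of TF *t* annotated to gene *g*.
   Footprints attributed to several TFs at identical coordinates (motif
   ambiguity, heterodimers) count toward every TF.
3. **Modules** — after row z-scoring, two k-means clusterings run on the same
   matrix, one over genes and one over TFs (k chosen by elbow + silhouette).
   Every (gene cluster, TF cluster) pairing is a candidate GRM, scored by its
   *differential-binding density*

   density(G, T) = Σ_{g∈G, t∈T} cell(g, t) / (|G| · |T|)

   computed on the unscaled matrix; the top pairings per expression direction
   (excluding single-TF clusters) are the reported GRMs. TF-centric network
   constructs — regulons, co-regulation subnetworks, feed-forward loops —
   are derived from the same bound-site table.
4. **Burden** — cohort variants are filtered (depth ≥ 30×, non-synonymous,
   AF_NFE < 0.01) and scored per individual over a gene set as the fraction
   of genes with ≥ 1 passing SNV in their locus (gene span ∪ associated ROC)
   and as SNVs per 100 kb of locus length; cohorts are compared with rank
   tests under BH correction, and patients are stratified by Ward clustering
   of per-GRM burden profiles.

A fully seeded synthetic-data generator (`grmkit.synthetic_data`) produces
every input layer with planted ground truth — negative-binomial counts with
planted fold-changes, ROC with a planted open/closed fraction, footprints
with planted gene × TF biclusters, and case/control variant tables with a
planted rate enrichment in module genes — so the whole pipeline is testable
without any sequencing data.

## Worked example

```python
import numpy as np
from grmkit import synthetic_data as sd, differential_analysis as da
from grmkit import chromatin_landscape as cl, binding as bd
from grmkit import grm_clustering as gc, variant_enrichment as ve

config = sd.SimulationConfig(n_genes=400, n_tfs=20, seed=11, planted_modules=(
    sd.PlantedModule(tf_indices=tuple(range(6)),
                     gene_indices=tuple(range(20)), direction="up"),
))
genes = sd.generate_gene_models(config)

# 1. expression signature
counts, groups, _ = sd.simulate_expression(config)
filtered = da.filter_low(counts)
results = da.differential_test(filtered, groups, da.tmm_factors(filtered))
signature = da.select_signature(results, lfc_threshold=1.0, alpha=0.05)
print(f"signature: {len(signature.up)} up, {len(signature.down)} down")

# 2. chromatin landscape
rocs, roc_counts, tfbs, _ = sd.simulate_landscape(config, genes)
acc = da.filter_low(roc_counts)
dca = da.differential_test(acc, groups, da.tmm_factors(acc))
annotated = cl.annotate_nearest_tss(rocs, genes)
cl.attach_dca(annotated, dca)
print("accessibility classes:", cl.classify_roc(annotated))

# 3. binding matrix and modules
bound = bd.call_bound(tfbs, p_threshold=0.01, condition="b")
matrix, _ = bd.build_matrix(bound, signature.up)
clustering = gc.double_kmeans(gc.row_zscore(matrix), k_rows=2, k_cols=2, seed=11)
(module,) = gc.select_modules(clustering, matrix, "up", top_n=1, tfbs=bound)
print(f"top module {module.name}: density={module.density:.2f}, "
      f"{len(module.gene_cluster)} genes x {len(module.tf_cluster)} TFs, "
      f"duplicate TFBS {module.duplicate_tfbs_fraction:.1%}")

# 4. cohort burden on the module genes
module_genes = sorted(module.gene_cluster)
cases, controls, _ = sd.simulate_cohorts(config, genes, annotated, module_genes)
loci = ve.build_loci(genes, annotated, module_genes)
case_ids = [f"case_{i+1:03d}" for i in range(config.n_cases)]
ctrl_ids = [f"ctrl_{i+1:03d}" for i in range(config.n_controls)]
case_b = ve.burden(ve.filter_variants(cases), loci, case_ids, "module")
ctrl_b = ve.burden(ve.filter_variants(controls), loci, ctrl_ids, "module")
(comp,) = ve.compare_cohorts([
    ("module fraction-mutated",
     [b.fraction_mutated for b in case_b],
     [b.fraction_mutated for b in ctrl_b], "mannwhitney"),
])
print(f"burden: cases {np.mean([b.fraction_mutated for b in case_b]):.2f} vs "
      f"controls {np.mean([b.fraction_mutated for b in ctrl_b]):.2f}, "
      f"BH-adjusted p = {comp.p_adjusted:.2g}")
```

Output:

```
signature: 34 up, 7 down
accessibility classes: {'open': 39, 'closed': 22, 'unchanged': 1478}
top module TF005_up: density=0.78, 22 genes x 6 TFs, duplicate TFBS 5.1%
burden: cases 0.26 vs controls 0.09, BH-adjusted p = 8.8e-11
```

Reading the numbers: 34 + 7 of 400 simulated genes pass the signature
thresholds (the generator planted ~10% differentially expressed genes); most
ROC are "unchanged", as expected when only a few percent of regions carry a
planted accessibility shift; the selected module recovers the planted 6-TF
block with a strong positive density (mean differential binding ≈ 0.8 per
cell) and a low duplicate-footprint share; and the planted 3× mutation-rate
enrichment in module genes makes case individuals carry passing SNVs in 26%
of module genes versus 9% in controls — a difference a 35 vs 35 rank test
resolves decisively.

The same stages are available from the shell: `grmkit simulate`,
`grmkit diffexp`, `grmkit landscape`, `grmkit bindmat`, `grmkit grm`,
`grmkit network`, `grmkit burden` (see `grmkit --help`).

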