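"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates, on one synthetic chromosome, the four data layers the
analysis consumes: (1) negative-binomial expression counts with planted
fold-changes between two small replicate groups; (2) regions of open
chromatin (ROC) placed around gene TSSs, with accessibility counts and a
planted open/closed fraction; (3) TF footprints inside ROC whose
condition-score differences carry planted gene x TF bicluster structure plus
Gaussian noise, with a configurable fraction of footprints duplicated under a
second TF name at identical coordinates; and (4) case/control cohort variant
tables with a planted mutation-rate enrichment in module genes.

Everything is driven by one :class:`SimulationConfig`; a fixed seed gives
byte-identical outputs. Ground truth (planted memberships and effects) is
returned alongside each layer so parameter-recovery tests can score the
pipeline end to end.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import chromatin_landscape, variant_enrichment
from .binding import TFBSRecord
from .io_formats import (
    GeneModel,
    GenomicInterval,
    VariantRecord,
    write_counts,
    write_gene_models,
    write_regions,
    write_vcf,
)
from .binding import write_tfbs

__all__ = [
    "PlantedModule",
    "SimulationConfig",
    "generate_gene_models",
    "simulate_expression",
    "simulate_binding_matrix",
    "simulate_landscape",
    "simulate_cohorts",
    "write_dataset",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedModule:
    """A planted gene x TF bicluster with a signed binding shift."""

    tf_indices: tuple
    gene_indices: tuple
    direction: str  # up | down
    shift: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in {"up", "down"}:
            raise ValueError(f"direction must be up/down, got {self.direction}")
        if self.shift <= 0:
            raise ValueError("binding shift must be positive")

    @property
    def signed_shift(self) -> float:
        return self.shift if self.direction == "up" else -self.shift


def _default_modules() -> tuple:
    # Mirrors the scale of the strongest observed modules: a compact 7-TF
    # cluster on 35 up-regulated genes and a 10-TF cluster on 70
    # down-regulated genes.
    return (
        PlantedModule(tf_indices=tuple(range(0, 7)), gene_indices=tuple(range(0, 35)),
                      direction="up", shift=1.0),
        PlantedModule(tf_indices=tuple(range(7, 17)), gene_indices=tuple(range(100, 170)),
                      direction="down", shift=1.0),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults follow the contrasted-lineage design the pipeline targets: three
    replicates per lineage, ~10% differentially expressed genes at planted
    |log2FC| = 3 with NB dispersion 0.05, a median of ~4 ROC per gene, a
    14.8% duplicate-TFBS rate, binding biclusters with unit shift over
    noise sd 0.2, and 35 vs 35 cohorts at 2 SNV/100kb baseline with a
    3-fold rate enrichment in module genes for cases.
    """

    n_genes: int = 2000
    n_tfs: int = 40
    n_samples_per_group: int = 3
    seed: int = 0
    # expression
    de_fraction: float = 0.10
    de_log2fc_mean: float = 3.0
    nb_dispersion: float = 0.05
    baseline_log_mean: float = float(np.log(200.0))
    baseline_log_sd: float = 1.0
    # chromatin landscape
    roc_per_gene_mean: float = 4.0
    roc_halfwindow: int = 50_000
    open_fraction: float = 0.03
    closed_fraction: float = 0.01
    accessibility_log2fc: float = 1.5
    # binding
    planted_modules: tuple = field(default_factory=_default_modules)
    binding_noise_sd: float = 0.2
    tfbs_per_roc_mean: float = 3.0
    module_site_prob: float = 0.8
    bound_prob_b: float = 0.9
    bound_prob_a: float = 0.5
    duplicate_tfbs_fraction: float = 0.148
    # cohorts
    n_cases: int = 35
    n_controls: int = 35
    base_mutation_rate: float = 2.0  # SNV per 100 kb per individual
    enrichment_factor: float = 3.0  # case rate multiplier in module genes
    p_synonymous: float = 0.3
    p_af_missing: float = 0.05
    p_af_rare: float = 0.7
    depth_mean: float = 40.0
    depth_sd: float = 8.0
    # genome layout
    gene_length: int = 10_000
    gene_spacing: int = 50_000

    def __post_init__(self) -> None:
        if not 0 <= self.de_fraction < 1:
            raise ValueError("de_fraction must be in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("negative-binomial dispersion must be positive")
        if self.enrichment_factor < 1:
            raise ValueError("enrichment factor must be >= 1")
        for m in self.planted_modules:
            if max(m.tf_indices, default=-1) >= self.n_tfs:
                raise ValueError("planted module TF index out of range")
            if max(m.gene_indices, default=-1) >= self.n_genes:
                raise ValueError("planted module gene index out of range")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _gene_id(i: int) -> str:
    return f"g{i:05d}"


def _tf_name(i: int) -> str:
    return f"TF{i:03d}"


def generate_gene_models(config: SimulationConfig) -> list[GeneModel]:
    """Non-overlapping gene spans tiled along one synthetic chromosome."""
    genes = []
    for i in range(config.n_genes):
        start = i * config.gene_spacing + 1000
        strand = "+" if i % 2 == 0 else "-"
        genes.append(GeneModel(_gene_id(i), "chr1", strand, start, start + config.gene_length))
    return genes


def _nb_counts(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws with variance mu + dispersion * mu^2."""
    r = 1.0 / dispersion
    p = r / (r + np.maximum(mean, 1e-12))
    return rng.negative_binomial(r, p)


@dataclass(frozen=True)
class ExpressionTruth:
    log2fc: pd.Series  # planted signed effects, indexed by gene id
    de_up: frozenset
    de_down: frozenset


def simulate_expression(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[pd.DataFrame, pd.Series, ExpressionTruth]:
    """Planted-fold-change negative-binomial counts for two replicate groups.

    The first ``round(de_fraction * n_genes)`` genes are differentially
    expressed at |log2FC| = ``de_log2fc_mean``; their signs honour the planted
    module directions (module genes in 'up' modules are up-regulated, and so
    on), remaining DE genes get random signs. Library sizes vary at most
    two-fold across samples. Returns (counts, sample->group labels, truth).
    """
    if config.n_samples_per_group < 2:
        raise ValueError("need >=2 samples per group")
    rng = config.rng() if rng is None else rng
    n = config.n_genes
    n_de = int(round(config.de_fraction * n))
    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=n)

    lfc = np.zeros(n)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    lfc[:n_de] = config.de_log2fc_mean * signs
    for module in config.planted_modules:
        for g in module.gene_indices:
            if g < n_de:
                lfc[g] = config.de_log2fc_mean * (1.0 if module.direction == "up" else -1.0)

    k = config.n_samples_per_group
    lib_factor = rng.uniform(0.75, 1.5, size=2 * k)
    mean_a = baseline[:, None] * lib_factor[None, :k]
    mean_b = (baseline * 2.0 ** lfc)[:, None] * lib_factor[None, k:]
    counts = np.concatenate(
        [_nb_counts(rng, mean_a, config.nb_dispersion), _nb_counts(rng, mean_b, config.nb_dispersion)],
        axis=1,
    )
    genes = [_gene_id(i) for i in range(n)]
    samples = [f"A_{j+1}" for j in range(k)] + [f"B_{j+1}" for j in range(k)]
    groups = pd.Series(["A"] * k + ["B"] * k, index=samples, name="group")
    truth = ExpressionTruth(
        log2fc=pd.Series(lfc[:n_de], index=genes[:n_de], name="log2fc"),
        de_up=frozenset(genes[i] for i in range(n_de) if lfc[i] > 0),
        de_down=frozenset(genes[i] for i in range(n_de) if lfc[i] < 0),
    )
    return pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=samples), groups, truth


def simulate_binding_matrix(
    n_genes: int,
    n_tfs: int,
    modules: Sequence[PlantedModule],
    noise_sd: float = 0.2,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Gene x TF matrix with planted bicluster blocks over Gaussian noise.

    Cells are N(0, noise_sd) except inside planted (gene, TF) blocks, which
    are shifted by the module's signed shift. Returns the matrix plus the
    planted row and column partitions (module index + 1, 0 = background) for
    recovery scoring.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    matrix = rng.normal(0.0, noise_sd, size=(n_genes, n_tfs))
    row_truth = np.zeros(n_genes, dtype=int)
    col_truth = np.zeros(n_tfs, dtype=int)
    for m_idx, module in enumerate(modules, start=1):
        gi = np.array(module.gene_indices, dtype=int)
        ti = np.array(module.tf_indices, dtype=int)
        if gi.max() >= n_genes or ti.max() >= n_tfs:
            raise ValueError("planted module indices out of range")
        matrix[np.ix_(gi, ti)] += module.signed_shift
        row_truth[gi] = m_idx
        col_truth[ti] = m_idx
    genes = [_gene_id(i) for i in range(n_genes)]
    tfs = [_tf_name(i) for i in range(n_tfs)]
    return (
        pd.DataFrame(matrix, index=pd.Index(genes, name="gene_id"), columns=tfs),
        pd.Series(row_truth, index=genes, name="module"),
        pd.Series(col_truth, index=tfs, name="module"),
    )


@dataclass(frozen=True)
class LandscapeTruth:
    open_rocs: frozenset
    closed_rocs: frozenset
    module_genes: tuple  # per planted module: frozenset of gene ids
    module_tfs: tuple  # per planted module: frozenset of TF names


def simulate_landscape(
    config: SimulationConfig,
    gene_models: Sequence[GeneModel],
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[GenomicInterval], pd.DataFrame, list[TFBSRecord], LandscapeTruth]:
    """ROC intervals, accessibility counts and TF footprints with planted structure.

    ROC are placed around each gene's TSS (Poisson count per gene, positions
    within +-roc_halfwindow) and then annotated to their actual nearest TSS;
    the planted binding shifts are keyed on that annotation so downstream
    recovery is self-consistent. A small fraction of ROC is planted
    open/closed beyond the accessibility threshold. Footprint condition-score
    differences are delta-shifted inside planted module cells and N(0, sd)
    elsewhere; a configurable fraction of footprints is duplicated under a
    second TF name at identical coordinates.
    """
    rng = config.rng() if rng is None else rng
    tf_names = [_tf_name(i) for i in range(config.n_tfs)]

    # --- ROC placement around TSSs
    rocs: list[GenomicInterval] = []
    n_roc_per_gene = rng.poisson(config.roc_per_gene_mean, size=len(gene_models))
    counter = 0
    for gene, n_roc in zip(gene_models, n_roc_per_gene):
        for _ in range(int(n_roc)):
            counter += 1
            center = gene.tss + int(rng.integers(-config.roc_halfwindow, config.roc_halfwindow + 1))
            width = int(rng.integers(200, 601))
            start = max(0, center - width // 2)
            rocs.append(GenomicInterval(gene.chrom, start, start + width, f"roc_{counter:06d}"))

    # --- accessibility counts with planted open/closed ROC
    n_roc = len(rocs)
    base = rng.lognormal(np.log(100.0), 0.8, size=n_roc)
    acc_lfc = np.zeros(n_roc)
    u = rng.uniform(size=n_roc)
    acc_lfc[u < config.open_fraction] = config.accessibility_log2fc
    closed_mask = (u >= config.open_fraction) & (u < config.open_fraction + config.closed_fraction)
    acc_lfc[closed_mask] = -config.accessibility_log2fc
    k = config.n_samples_per_group
    lib_factor = rng.uniform(0.75, 1.5, size=2 * k)
    mean_a = base[:, None] * lib_factor[None, :k]
    mean_b = (base * 2.0 ** acc_lfc)[:, None] * lib_factor[None, k:]
    roc_counts = pd.DataFrame(
        np.concatenate(
            [_nb_counts(rng, mean_a, config.nb_dispersion), _nb_counts(rng, mean_b, config.nb_dispersion)],
            axis=1,
        ),
        index=pd.Index([r.id for r in rocs], name="roc_id"),
        columns=[f"A_{j+1}" for j in range(k)] + [f"B_{j+1}" for j in range(k)],
    )

    # --- module membership keyed on the nearest-TSS annotation
    annotated = chromatin_landscape.annotate_nearest_tss(rocs, gene_models)
    roc_gene = {a.interval.id: a.gene_id for a in annotated}
    module_gene_sets = tuple(
        frozenset(_gene_id(i) for i in m.gene_indices) for m in config.planted_modules
    )
    module_tf_sets = tuple(
        frozenset(_tf_name(i) for i in m.tf_indices) for m in config.planted_modules
    )
    shift_of_gene_tf: dict[tuple[str, str], float] = {}
    for module, genes, tfs in zip(config.planted_modules, module_gene_sets, module_tf_sets):
        for g in genes:
            for t in tfs:
                shift_of_gene_tf[(g, t)] = module.signed_shift

    # --- footprints
    records: list[TFBSRecord] = []
    site_no = 0

    def _new_site(roc: GenomicInterval, tf: str, gene: str) -> None:
        nonlocal site_no
        site_no += 1
        width = int(rng.integers(10, 21))
        start = int(rng.integers(roc.start, max(roc.start + 1, roc.end - width)))
        shift = shift_of_gene_tf.get((gene, tf), 0.0)
        diff = shift + rng.normal(0.0, config.binding_noise_sd)
        score_a = max(0.0, rng.normal(3.0, 0.5))
        p_b = (
            rng.uniform(0.0, 0.009)
            if rng.uniform() < config.bound_prob_b
            else rng.uniform(0.02, 1.0)
        )
        p_a = (
            rng.uniform(0.0, 0.009)
            if rng.uniform() < config.bound_prob_a
            else rng.uniform(0.02, 1.0)
        )
        records.append(
            TFBSRecord(
                tfbs_id=f"tfbs_{site_no:07d}",
                tf=tf,
                motif_id=f"M{tf}",
                chrom=roc.chrom,
                start=start,
                end=start + width,
                strand="+" if rng.uniform() < 0.5 else "-",
                motif_score=float(rng.uniform(5.0, 15.0)),
                score_a=score_a,
                score_b=score_a + diff,
                p_bound_a=float(p_a),
                p_bound_b=float(p_b),
                roc_id=roc.id,
                gene_id=gene,
            )
        )

    module_of_gene: dict[str, int] = {}
    for m_idx, genes in enumerate(module_gene_sets):
        for g in genes:
            module_of_gene[g] = m_idx
    for roc in rocs:
        gene = roc_gene[roc.id]
        for _ in range(int(rng.poisson(config.tfbs_per_roc_mean))):
            _new_site(roc, tf_names[int(rng.integers(config.n_tfs))], gene)
        m_idx = module_of_gene.get(gene)
        if m_idx is not None:
            for tf in sorted(module_tf_sets[m_idx]):
                if rng.uniform() < config.module_site_prob:
                    _new_site(roc, tf, gene)

    # --- duplicate a fraction of footprints under a second TF name
    f = config.duplicate_tfbs_fraction
    if f > 0:
        q = f / (2.0 - f)  # per-site copy probability so the final duplicate share is f
        copies = []
        for rec in records:
            if rng.uniform() < q:
                other = tf_names[int(rng.integers(config.n_tfs))]
                while other == rec.tf:
                    other = tf_names[int(rng.integers(config.n_tfs))]
                site_no += 1
                copies.append(
                    dataclasses.replace(rec, tfbs_id=f"tfbs_{site_no:07d}", tf=other,
                                        motif_id=f"M{other}")
                )
        records.extend(copies)

    truth = LandscapeTruth(
        open_rocs=frozenset(r.id for r, l in zip(rocs, acc_lfc) if l > 0),
        closed_rocs=frozenset(r.id for r, l in zip(rocs, acc_lfc) if l < 0),
        module_genes=module_gene_sets,
        module_tfs=module_tf_sets,
    )
    return rocs, roc_counts, records, truth


@dataclass(frozen=True)
class CohortTruth:
    case_rates: pd.Series  # per gene, SNV/100kb rate in cases
    control_rates: pd.Series


def simulate_cohorts(
    config: SimulationConfig,
    gene_models: Sequence[GeneModel],
    annotated_rocs: Sequence[chromatin_landscape.AnnotatedROC],
    module_genes: Sequence[str],
    rng: Optional[np.random.Generator] = None,
    case_prefix: str = "case",
    control_prefix: str = "ctrl",
) -> tuple[list[VariantRecord], list[VariantRecord], CohortTruth]:
    """Per-individual Poisson variant tables with planted module enrichment.

    For each individual and gene locus (gene span union its ROC), the SNV
    count is Poisson(locus length x rate / 100kb); the rate is multiplied by
    the enrichment factor for module genes in cases. Each SNV gets an AF_NFE
    drawn from a mixture with mass below and above 0.01 (and a small missing
    fraction), a consequence label (synonymous with configurable
    probability), and a depth from a discretised normal around the target
    coverage, so the downstream filters have work to do.
    """
    if case_prefix == control_prefix:
        raise ValueError("case and control cohorts would share sample ids")
    rng = config.rng() if rng is None else rng
    module_set = set(module_genes)
    unknown = module_set - {g.gene_id for g in gene_models}
    if unknown:
        raise ValueError(f"module genes absent from gene models: {sorted(unknown)}")
    loci = variant_enrichment.build_loci(
        gene_models, annotated_rocs, [g.gene_id for g in gene_models]
    )
    cases = [f"{case_prefix}_{i+1:03d}" for i in range(config.n_cases)]
    controls = [f"{control_prefix}_{i+1:03d}" for i in range(config.n_controls)]

    lengths = np.array([l.total_length for l in loci], dtype=float)
    base_lam = lengths * config.base_mutation_rate / 1e5
    is_module = np.array([l.gene_id in module_set for l in loci])

    def _draw(individuals: list[str], enriched: bool) -> list[VariantRecord]:
        lam = base_lam.copy()
        if enriched:
            lam[is_module] *= config.enrichment_factor
        counts = rng.poisson(lam[:, None], size=(len(loci), len(individuals)))
        out: list[VariantRecord] = []
        for li, locus in enumerate(loci):
            starts = np.array([s for s, _ in locus.intervals])
            widths = np.array([e - s for s, e in locus.intervals], dtype=float)
            cum = np.cumsum(widths) / widths.sum()
            for pi, person in enumerate(individuals):
                for _ in range(int(counts[li, pi])):
                    piece = int(np.searchsorted(cum, rng.uniform()))
                    pos0 = int(starts[piece] + rng.integers(0, widths[piece]))
                    ref, alt = rng.choice(_BASES, size=2, replace=False)
                    u = rng.uniform()
                    if u < config.p_af_missing:
                        af = None
                    elif u < config.p_af_missing + config.p_af_rare:
                        af = float(rng.uniform(1e-4, 0.009))
                    else:
                        af = float(rng.uniform(0.02, 0.5))
                    csq = (
                        "synonymous_variant"
                        if rng.uniform() < config.p_synonymous
                        else "missense_variant"
                    )
                    depth = max(0, int(round(rng.normal(config.depth_mean, config.depth_sd))))
                    out.append(
                        VariantRecord(
                            chrom=locus.chrom,
                            pos=pos0 + 1,
                            ref=str(ref),
                            alt=str(alt),
                            af_nfe=af,
                            consequence=csq,
                            depth=depth,
                            carriers=frozenset({person}),
                        )
                    )
        return out

    case_records = _draw(cases, enriched=True)
    control_records = _draw(controls, enriched=False)
    gene_ids = [l.gene_id for l in loci]
    case_rates = pd.Series(
        np.where(is_module, config.base_mutation_rate * config.enrichment_factor,
                 config.base_mutation_rate),
        index=gene_ids,
    )
    control_rates = pd.Series(np.full(len(loci), config.base_mutation_rate), index=gene_ids)
    return case_records, control_records, CohortTruth(case_rates, control_rates)


def write_dataset(config: SimulationConfig, outdir) -> dict:
    """Generate every pipeline input under ``outdir`` and return file paths.

    Writes expression counts + design, gene models, ROC BED + accessibility
    counts, the TFBS table, case/control VCFs and a ground-truth JSON.
    Deterministic: the same config yields byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = config.rng()
    genes = generate_gene_models(config)
    counts, groups, expr_truth = simulate_expression(config, rng)
    rocs, roc_counts, tfbs, land_truth = simulate_landscape(config, genes, rng)
    annotated = chromatin_landscape.annotate_nearest_tss(rocs, genes)
    module_genes = sorted(set().union(*land_truth.module_genes)) if land_truth.module_genes else []
    case_records, control_records, cohort_truth = simulate_cohorts(
        config, genes, annotated, module_genes, rng
    )

    paths = {
        "counts": outdir / "expression_counts.tsv",
        "design": outdir / "design.tsv",
        "genes": outdir / "genes.tsv",
        "rocs": outdir / "rocs.bed",
        "roc_counts": outdir / "roc_counts.tsv",
        "tfbs": outdir / "tfbs.tsv",
        "cases_vcf": outdir / "cases.vcf",
        "controls_vcf": outdir / "controls.vcf",
        "truth": outdir / "ground_truth.json",
    }
    write_counts(paths["counts"], counts)
    pd.DataFrame({"sample": groups.index, "group": groups.values}).to_csv(
        paths["design"], sep="\t", index=False
    )
    write_gene_models(paths["genes"], genes)
    write_regions(paths["rocs"], rocs)
    write_counts(paths["roc_counts"], roc_counts)
    write_tfbs(paths["tfbs"], tfbs)
    cases = sorted({s for r in case_records for s in r.carriers} | {f"case_{i+1:03d}" for i in range(config.n_cases)})
    controls = sorted({s for r in control_records for s in r.carriers} | {f"ctrl_{i+1:03d}" for i in range(config.n_controls)})
    write_vcf(paths["cases_vcf"], case_records, cases)
    write_vcf(paths["controls_vcf"], control_records, controls)
    truth = {
        "de_up": sorted(expr_truth.de_up),
        "de_down": sorted(expr_truth.de_down),
        "planted_log2fc": expr_truth.log2fc.to_dict(),
        "open_rocs": sorted(land_truth.open_rocs),
        "closed_rocs": sorted(land_truth.closed_rocs),
        "module_genes": [sorted(s) for s in land_truth.module_genes],
        "module_tfs": [sorted(s) for s in land_truth.module_tfs],
        "case_rates": cohort_truth.case_rates.to_dict(),
    }
    with open(paths["truth"], "w", encoding="utf-8") as handle:
        json.dump(truth, handle, indent=1, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
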