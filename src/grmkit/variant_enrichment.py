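"""Rare-variant filtering and gene-set burden analysis.

Variants are filtered on read depth (>= 30x), consequence (synonymous
excluded) and population rarity (AF_NFE < 0.01, with a missing frequency
treated as rare). Burden is quantified per individual over a named gene set
as (i) the fraction of set genes with at least one passing variant in their
locus and (ii) passing variants per 100 kb of locus length, where a gene
locus is the union of the gene span and its associated regions of open
chromatin. Cohorts are compared with rank tests under Benjamini-Hochberg
correction, and patients are stratified by hierarchical clustering of their
per-gene-set burden profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .binding import TFBSRecord
from .chromatin_landscape import AnnotatedROC
from .differential_analysis import bh_adjust
from .io_formats import GeneModel, VariantRecord

__all__ = [
    "GeneLocus",
    "BurdenRecord",
    "CohortComparison",
    "PatientClusters",
    "filter_variants",
    "merge_intervals",
    "build_loci",
    "burden",
    "per_gene_prevalence",
    "compare_cohorts",
    "cluster_patients",
    "tfbs_variant_overlap",
]

AF_MAX = 0.01
MIN_DEPTH = 30
EXCLUDED_CONSEQUENCES = frozenset({"synonymous_variant"})


@dataclass(frozen=True)
class GeneLocus:
    """A gene's variant-scoring territory: gene span merged with its ROC."""

    gene_id: str
    chrom: str
    intervals: tuple  # ((start, end), ...) disjoint, sorted, 0-based half-open

    @property
    def total_length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def contains(self, pos0: int) -> bool:
        return any(s <= pos0 < e for s, e in self.intervals)


@dataclass(frozen=True)
class BurdenRecord:
    individual_id: str
    gene_set_name: str
    fraction_mutated: float
    snv_per_100kb: float


@dataclass(frozen=True)
class CohortComparison:
    contrast: str
    statistic: float
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class PatientClusters:
    linkage: np.ndarray
    labels: pd.Series
    k: int
    newick: str
    first_split: tuple  # (ids in left branch, ids in right branch)


def filter_variants(
    records: Iterable[VariantRecord],
    af_max: float = AF_MAX,
    min_depth: int = MIN_DEPTH,
    exclude_consequences: frozenset = EXCLUDED_CONSEQUENCES,
    drop_missing_af: bool = False,
) -> list[VariantRecord]:
    """Keep rare, adequately covered, non-synonymous variants.

    A record passes iff depth >= min_depth, its consequence is not excluded,
    and AF_NFE < af_max (strict); a missing AF_NFE counts as rare unless
    ``drop_missing_af``.
    """
    passing = []
    for rec in records:
        if rec.depth < min_depth or rec.consequence in exclude_consequences:
            continue
        if rec.af_nfe is None:
            if drop_missing_af:
                continue
        elif rec.af_nfe >= af_max:
            continue
        passing.append(rec)
    return passing


def merge_intervals(intervals: Iterable[tuple]) -> tuple:
    """Union of half-open intervals: sorted, disjoint (idempotent, order-free)."""
    ordered = sorted(intervals)
    merged: list[list] = []
    for s, e in ordered:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def build_loci(
    gene_models: Sequence[GeneModel],
    annotated_rocs: Sequence[AnnotatedROC],
    gene_set: Iterable[str],
) -> list[GeneLocus]:
    """Per gene: merge the gene span with its annotated ROC intervals."""
    genes = {g.gene_id: g for g in gene_models}
    wanted = sorted(set(gene_set))
    missing = [g for g in wanted if g not in genes]
    if missing:
        raise ValueError(f"gene set members absent from gene models: {missing}")
    roc_by_gene: dict[str, list[tuple]] = {}
    for roc in annotated_rocs:
        roc_by_gene.setdefault(roc.gene_id, []).append((roc.interval.start, roc.interval.end))
    loci = []
    for gene_id in wanted:
        model = genes[gene_id]
        pieces = [(model.start, model.end)] + roc_by_gene.get(gene_id, [])
        loci.append(GeneLocus(gene_id=gene_id, chrom=model.chrom, intervals=merge_intervals(pieces)))
    return loci


def _variant_gene_hits(
    variants: Sequence[VariantRecord], loci: Sequence[GeneLocus]
) -> list[tuple[int, str]]:
    """(variant index, gene_id) pairs for every variant inside a locus interval."""
    by_chrom: dict[str, list[int]] = {}
    for i, v in enumerate(variants):
        by_chrom.setdefault(v.chrom, []).append(i)
    pos_by_chrom = {
        chrom: (np.array([variants[i].pos0 for i in idx]), np.array(idx))
        for chrom, idx in by_chrom.items()
    }
    for chrom, (pos, idx) in pos_by_chrom.items():
        order = np.argsort(pos, kind="stable")
        pos_by_chrom[chrom] = (pos[order], idx[order])
    hits: list[tuple[int, str]] = []
    for locus in loci:
        entry = pos_by_chrom.get(locus.chrom)
        if entry is None:
            continue
        pos, idx = entry
        for s, e in locus.intervals:
            lo, hi = np.searchsorted(pos, [s, e])
            for j in idx[lo:hi]:
                hits.append((int(j), locus.gene_id))
    return hits


def burden(
    passing_variants: Sequence[VariantRecord],
    loci: Sequence[GeneLocus],
    individuals: Sequence[str],
    gene_set_name: str,
) -> list[BurdenRecord]:
    """Per-individual burden over one gene set.

    fraction_mutated = (# set genes whose locus holds >=1 variant the
    individual carries) / (# set genes); snv_per_100kb = 1e5 * (# carried
    passing variants summed over set loci) / (total locus length). A variant
    overlapping several gene loci counts once per locus.
    """
    if not loci:
        raise ValueError("empty gene set")
    total_length = sum(l.total_length for l in loci)
    hits = _variant_gene_hits(passing_variants, loci)
    genes_hit: dict[str, set[str]] = {ind: set() for ind in individuals}
    snvs: dict[str, int] = {ind: 0 for ind in individuals}
    for var_idx, gene_id in hits:
        for carrier in passing_variants[var_idx].carriers:
            if carrier in genes_hit:
                genes_hit[carrier].add(gene_id)
                snvs[carrier] += 1
    return [
        BurdenRecord(
            individual_id=ind,
            gene_set_name=gene_set_name,
            fraction_mutated=len(genes_hit[ind]) / len(loci),
            snv_per_100kb=1e5 * snvs[ind] / total_length,
        )
        for ind in individuals
    ]


def per_gene_prevalence(
    passing_variants: Sequence[VariantRecord],
    loci: Sequence[GeneLocus],
    cohort: Sequence[str],
) -> pd.Series:
    """Per gene: fraction of cohort individuals carrying >=1 passing variant."""
    cohort_set = set(cohort)
    carriers_by_gene: dict[str, set[str]] = {l.gene_id: set() for l in loci}
    for var_idx, gene_id in _variant_gene_hits(passing_variants, loci):
        carriers_by_gene[gene_id] |= passing_variants[var_idx].carriers & cohort_set
    return pd.Series(
        {g: len(c) / len(cohort) for g, c in carriers_by_gene.items()}, name="prevalence"
    ).sort_index()


def paired_prevalence(prev_a: pd.Series, prev_b: pd.Series) -> pd.DataFrame:
    """Two-cohort prevalence pairs, dropping genes with no variant in either."""
    table = pd.DataFrame({"cohort_a": prev_a, "cohort_b": prev_b}).fillna(0.0)
    return table[(table > 0).any(axis=1)]


def compare_cohorts(
    contrasts: Sequence[tuple],
    alpha: float = 0.05,
) -> list[CohortComparison]:
    """Rank-test a family of burden contrasts with BH correction across it.

    Each contrast is (label, values_a, values_b, kind) with kind
    'mannwhitney' (independent cohorts, two-sided) or 'wilcoxon' (paired
    set-vs-set within a cohort). All-tied inputs yield p = 1 with a warning.
    """
    stats_p = []
    for label, a, b, kind in contrasts:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if len(a) < 3 or len(b) < 3:
            raise ValueError(f"contrast {label}: need >=3 individuals per side")
        try:
            with warnings.catch_warnings():
                # fully tied inputs trigger benign division warnings inside scipy
                warnings.simplefilter("ignore", RuntimeWarning)
                if kind == "mannwhitney":
                    res = stats.mannwhitneyu(a, b, alternative="two-sided")
                elif kind == "wilcoxon":
                    res = stats.wilcoxon(a, b, alternative="two-sided")
                else:
                    raise ValueError(f"unknown test kind {kind!r}")
            stat, p = float(res.statistic), float(res.pvalue)
        except ValueError as exc:
            if "zero" in str(exc).lower() or "identical" in str(exc).lower():
                warnings.warn(f"contrast {label}: all values tied; p set to 1")
                stat, p = np.nan, 1.0
            else:
                raise
        if not np.isfinite(p):
            warnings.warn(f"contrast {label}: degenerate test; p set to 1")
            stat, p = np.nan, 1.0
        stats_p.append((label, stat, p))
    adjusted = bh_adjust([p for _, _, p in stats_p])
    return [
        CohortComparison(contrast=label, statistic=stat, p_raw=p, p_adjusted=float(q))
        for (label, stat, p), q in zip(stats_p, adjusted)
    ]


def _newick(node, names) -> str:
    if node.is_leaf():
        return names[node.id]
    left = _newick(node.get_left(), names)
    right = _newick(node.get_right(), names)
    return f"({left},{right}):{node.dist:.6g}"


def cluster_patients(
    burden_matrix: pd.DataFrame,
    k: Optional[int] = None,
    k_range: Iterable[int] = range(2, 9),
) -> PatientClusters:
    """Stratify individuals by their per-gene-set burden profile.

    Columns (gene sets) are z-scored, then agglomerative clustering with Ward
    linkage on Euclidean distance. Flat labels are cut at ``k`` when given,
    else at the k in ``k_range`` maximising mean silhouette. The first-branch
    split (two-cluster cut) is reported as the top-level patient partition.
    """
    from sklearn.metrics import silhouette_score

    if burden_matrix.shape[0] < 3 or burden_matrix.shape[1] < 2:
        raise ValueError("need >=3 individuals and >=2 gene sets")
    values = burden_matrix.to_numpy(dtype=float)
    sd = values.std(axis=0, ddof=0)
    if (sd == 0).all():
        raise ValueError("no structure: burden matrix is constant")
    keep = sd > 0
    z = (values[:, keep] - values[:, keep].mean(axis=0)) / sd[keep]
    linkage = hierarchy.ward(z)
    if k is None:
        best, best_score = None, -np.inf
        for kk in k_range:
            if not 2 <= kk < z.shape[0]:
                continue
            lab = hierarchy.fcluster(linkage, kk, criterion="maxclust")
            if len(np.unique(lab)) < 2:
                continue
            score = silhouette_score(z, lab)
            if score > best_score:
                best, best_score = kk, score
        k = best if best is not None else 2
    labels = hierarchy.fcluster(linkage, k, criterion="maxclust")
    two = hierarchy.fcluster(linkage, 2, criterion="maxclust")
    ids = list(burden_matrix.index)
    first_split = (
        tuple(i for i, c in zip(ids, two) if c == two[0]),
        tuple(i for i, c in zip(ids, two) if c != two[0]),
    )
    tree = hierarchy.to_tree(linkage)
    return PatientClusters(
        linkage=linkage,
        labels=pd.Series(labels, index=burden_matrix.index, name="cluster"),
        k=int(k),
        newick=f"({_newick(tree.get_left(), ids)},{_newick(tree.get_right(), ids)});",
        first_split=first_split,
    )


def tfbs_variant_overlap(
    passing_variants: Sequence[VariantRecord], bound_tfbs: Sequence[TFBSRecord]
) -> list[tuple[VariantRecord, TFBSRecord, str]]:
    """Variants falling inside bound footprints, one row per (variant, TFBS).

    VCF positions are converted to the internal 0-based convention before the
    half-open containment test; duplicated footprints under several TF names
    yield one row per TF.
    """
    by_chrom: dict[str, list[TFBSRecord]] = {}
    for rec in bound_tfbs:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    out = []
    for var in passing_variants:
        for rec in by_chrom.get(var.chrom, []):
            if rec.start <= var.pos0 < rec.end:
                out.append((var, rec, rec.tf))
    return out
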