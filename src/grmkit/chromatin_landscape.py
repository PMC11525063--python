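"""Per-gene chromatin landscape: nearest-TSS annotation of regions of open
chromatin (ROC), open/closed/unchanged classification of differential
accessibility, landscape summaries, and the robust accessibility-vs-expression
regression.

A ROC is assigned to the gene whose TSS is closest to the ROC midpoint on the
same chromosome (ties go to the lexicographically smaller gene id). ROC are
classified "open" when accessibility is significantly higher in the second
condition (q <= alpha and log2FC >= +tau), "closed" for the mirror image, and
"unchanged" otherwise; non-significant ROC remain part of the landscape, only
the class label differs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io_formats import GeneModel, GenomicInterval

__all__ = [
    "AnnotatedROC",
    "RobustFit",
    "annotate_nearest_tss",
    "attach_dca",
    "classify_roc",
    "landscape_summary",
    "overlap_percent",
    "significant_roc_percent",
    "gene_landscapes",
    "robust_line_fit",
    "robust_regression",
    "write_annotated",
]

logger = logging.getLogger(__name__)

DEFAULT_TAU = 0.68  # |log2FC| of accessibility matching q <= 0.05


@dataclass
class AnnotatedROC:
    """A ROC annotated to its nearest-TSS gene, with optional DCA statistics."""

    interval: GenomicInterval
    gene_id: str
    tss_distance: int  # signed: (midpoint - TSS), strand-oriented
    dca_log2fc: float = np.nan
    dca_q: float = np.nan
    dca_class: Optional[str] = None  # open | closed | unchanged


@dataclass(frozen=True)
class RobustFit:
    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 or np.isnan(self.r_squared)):
            raise ValueError(f"r_squared {self.r_squared} outside [0,1]")


def annotate_nearest_tss(
    rocs: Sequence[GenomicInterval], gene_models: Sequence[GeneModel]
) -> list[AnnotatedROC]:
    """Assign each ROC to the gene with the nearest TSS on its chromosome.

    Distance is |midpoint - TSS| with midpoint = floor((start+end)/2); exact
    ties are broken by the smaller gene id. ROC on chromosomes without any
    gene are dropped (the count is logged).
    """
    if not gene_models:
        raise ValueError("empty gene model set")
    by_chrom: dict[str, tuple[np.ndarray, list[str], list[str]]] = {}
    for chrom in {g.chrom for g in gene_models}:
        genes = sorted(
            (g for g in gene_models if g.chrom == chrom), key=lambda g: (g.tss, g.gene_id)
        )
        by_chrom[chrom] = (
            np.array([g.tss for g in genes], dtype=np.int64),
            [g.gene_id for g in genes],
            [g.strand for g in genes],
        )

    annotated: list[AnnotatedROC] = []
    dropped = 0
    for roc in rocs:
        entry = by_chrom.get(roc.chrom)
        if entry is None:
            dropped += 1
            continue
        tss, gene_ids, strands = entry
        mid = roc.midpoint
        dist = np.abs(tss - mid)
        ties = np.flatnonzero(dist == dist.min())
        j = min((int(t) for t in ties), key=lambda idx: gene_ids[idx])
        signed = mid - int(tss[j])
        if strands[j] == "-":
            signed = -signed
        annotated.append(AnnotatedROC(interval=roc, gene_id=gene_ids[j], tss_distance=signed))
    if dropped:
        logger.info("dropped %d ROC on chromosomes without gene models", dropped)
    return annotated


def attach_dca(annotated: Iterable[AnnotatedROC], dca_results: pd.DataFrame) -> list[AnnotatedROC]:
    """Copy log2fc and fdr from a differential-accessibility table (indexed by ROC id)."""
    out = list(annotated)
    for roc in out:
        if roc.interval.id in dca_results.index:
            row = dca_results.loc[roc.interval.id]
            roc.dca_log2fc = float(row["log2fc"])
            roc.dca_q = float(row["fdr"])
    return out


def classify_roc(
    annotated: Iterable[AnnotatedROC], alpha: float = 0.05, tau: float = DEFAULT_TAU
) -> dict[str, int]:
    """Set dca_class on each ROC and return {open, closed, unchanged} counts."""
    counts = {"open": 0, "closed": 0, "unchanged": 0}
    for roc in annotated:
        if roc.dca_q <= alpha and roc.dca_log2fc >= tau:
            roc.dca_class = "open"
        elif roc.dca_q <= alpha and roc.dca_log2fc <= -tau:
            roc.dca_class = "closed"
        else:
            roc.dca_class = "unchanged"
        counts[roc.dca_class] += 1
    return counts


def overlap_percent(n_annotated_signature_genes: int, n_signature_genes: int) -> int:
    """Share of signature genes with >=1 annotated ROC, as a whole percent."""
    if n_signature_genes <= 0:
        raise ValueError("empty signature")
    return round(100 * n_annotated_signature_genes / n_signature_genes)


def significant_roc_percent(n_significant: int, n_total: int) -> float:
    """Share of all ROC with significant accessibility change, one decimal."""
    if n_total <= 0:
        raise ValueError("no ROC")
    return round(100 * n_significant / n_total, 1)


def landscape_summary(
    annotated: Sequence[AnnotatedROC],
    signature_genes: Iterable[str],
    alpha: float = 0.05,
    tau: float = DEFAULT_TAU,
) -> dict:
    """Summarise how the ROC universe covers a gene signature.

    Returns the number of ROC annotated to signature genes, the number of
    signature genes with at least one ROC, their overlap percent (whole
    percent), the median ROC count per annotated signature gene, and the
    percent of all ROC that pass the significance gate (one decimal).
    """
    signature = set(signature_genes)
    if not signature:
        raise ValueError("empty signature")
    per_gene: dict[str, int] = {}
    n_sig_roc = 0
    n_significant = 0
    for roc in annotated:
        if roc.dca_q <= alpha and abs(roc.dca_log2fc) >= tau:
            n_significant += 1
        if roc.gene_id in signature:
            n_sig_roc += 1
            per_gene[roc.gene_id] = per_gene.get(roc.gene_id, 0) + 1
    return {
        "n_roc_signature": n_sig_roc,
        "n_signature_genes_with_roc": len(per_gene),
        "overlap_percent": overlap_percent(len(per_gene), len(signature)),
        "median_roc_per_gene": float(np.median(list(per_gene.values()))) if per_gene else 0.0,
        "significant_roc_percent": significant_roc_percent(n_significant, len(annotated)),
    }


def gene_landscapes(annotated: Sequence[AnnotatedROC]) -> pd.DataFrame:
    """Per-gene landscape: ROC count and mean accessibility log2FC."""
    rows = [(r.gene_id, r.interval.id, r.dca_log2fc) for r in annotated]
    table = pd.DataFrame(rows, columns=["gene_id", "roc_id", "dca_log2fc"])
    grouped = table.groupby("gene_id").agg(
        n_roc=("roc_id", "size"), mean_dca_log2fc=("dca_log2fc", "mean")
    )
    return grouped


def robust_line_fit(x, y, c: float = 4.685, max_iter: int = 100) -> RobustFit:
    """Robust line fit by IRLS with Tukey bisquare loss (tuning constant c).

    Initialised from ordinary least squares with MAD residual scale, as in
    M-type robust regression; the fit diagnostic is a weighted R^2,
    1 - sum(w e^2) / sum(w (y - weighted mean)^2), with converged weights.
    A perfect linear relation (zero MAD) short-circuits to the OLS line.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >=3 paired points")
    design = sm.add_constant(x)
    ols = sm.OLS(y, design).fit()
    resid = y - ols.fittedvalues
    if np.median(np.abs(resid - np.median(resid))) == 0:
        r2 = 1.0 if np.allclose(resid, 0) else float(np.clip(ols.rsquared, 0, 1))
        return RobustFit(float(ols.params[1]), float(ols.params[0]), r2, x.size)
    rlm = sm.RLM(y, design, M=sm.robust.norms.TukeyBiweight(c=c))
    import warnings as _warnings

    with _warnings.catch_warnings():
        # a perfect fit of the downweighted majority is a success, not a failure
        _warnings.simplefilter("ignore")
        fit = rlm.fit(maxiter=max_iter)
    w = fit.weights
    if not np.isfinite(fit.params).all():
        raise RuntimeError("robust fit did not converge")
    yhat = fit.fittedvalues
    ybar = np.average(y, weights=w) if w.sum() > 0 else y.mean()
    ss_res = float(np.sum(w * (y - yhat) ** 2))
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return RobustFit(float(fit.params[1]), float(fit.params[0]), float(np.clip(r2, 0, 1)), x.size)


def robust_regression(landscapes: pd.DataFrame, deg_results: pd.DataFrame) -> RobustFit:
    """Robust fit of mean accessibility change (y) on expression log2FC (x).

    ``landscapes`` comes from :func:`gene_landscapes`; ``deg_results`` is a
    differential-expression table indexed by gene id with a log2fc column.
    Genes present in both with finite values are used.
    """
    joined = landscapes.join(deg_results[["log2fc"]], how="inner").dropna(
        subset=["mean_dca_log2fc", "log2fc"]
    )
    if len(joined) < 3:
        raise ValueError("need >=3 genes with both mean DCA and expression log2FC")
    return robust_line_fit(joined["log2fc"].to_numpy(), joined["mean_dca_log2fc"].to_numpy())


def write_annotated(path, annotated: Sequence[AnnotatedROC]) -> None:
    """Write annotated ROC as a TSV (deterministic: sorted by ROC id)."""
    rows = [
        (
            r.interval.id,
            r.interval.chrom,
            r.interval.start,
            r.interval.end,
            r.gene_id,
            r.tss_distance,
            r.dca_log2fc,
            r.dca_q,
            r.dca_class if r.dca_class is not None else "",
        )
        for r in sorted(annotated, key=lambda r: r.interval.id)
    ]
    pd.DataFrame(
        rows,
        columns=[
            "roc_id",
            "chrom",
            "start",
            "end",
            "gene_id",
            "tss_distance",
            "dca_log2fc",
            "dca_q",
            "dca_class",
        ],
    ).to_csv(path, sep="\t", index=False)
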