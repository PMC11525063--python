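"""Transcription-factor footprint handling: bound-site calling, per-site
differential binding, the gene x TF binding matrix, and duplicate-TFBS
accounting.

A TFBS carries two condition footprint scores (a = baseline lineage, b =
contrast lineage) and per-condition bound p-values; "bound" means p < 0.01 in
the chosen condition. Differential binding is score_b - score_a. The binding
matrix averages differential binding over all bound sites of a TF annotated
to a gene; footprints at identical coordinates attributed to several TFs
(motif ambiguity, heterodimers) contribute to every one of their TFs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TFBSRecord",
    "empirical_pvalue",
    "call_bound",
    "differential_binding",
    "build_matrix",
    "duplicate_fraction",
    "read_tfbs",
    "write_tfbs",
]

logger = logging.getLogger(__name__)

BOUND_P_THRESHOLD = 0.01

_TFBS_COLUMNS = [
    "tfbs_id",
    "tf",
    "motif_id",
    "chrom",
    "start",
    "end",
    "strand",
    "motif_score",
    "score_a",
    "score_b",
    "p_bound_a",
    "p_bound_b",
    "roc_id",
    "gene_id",
]


@dataclass
class TFBSRecord:
    """One TF footprint with per-condition scores and optional annotation."""

    tfbs_id: str
    tf: str
    motif_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    motif_score: float = 0.0
    score_a: float = 0.0
    score_b: float = 0.0
    p_bound_a: Optional[float] = None
    p_bound_b: Optional[float] = None
    roc_id: Optional[str] = None
    gene_id: Optional[str] = None

    @property
    def diff(self) -> float:
        """Differential binding: contrast-condition score minus baseline score."""
        return self.score_b - self.score_a

    @property
    def coordinates(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def empirical_pvalue(score: float, null_scores) -> float:
    """Right-tail plug-in empirical p: (1 + #null >= score) / (1 + #null)."""
    null = np.asarray(null_scores, dtype=float)
    if null.size == 0:
        raise ValueError("empty null sample")
    return float((1 + np.sum(null >= score)) / (1 + null.size))


def call_bound(
    tfbs: Iterable[TFBSRecord],
    p_threshold: float = BOUND_P_THRESHOLD,
    condition: str = "b",
    null_scores=None,
) -> list[TFBSRecord]:
    """Select footprints bound in one condition (p < threshold, strict).

    Uses the stored per-condition bound p-value; when it is absent a null
    score sample must be supplied, from which a right-tail empirical p is
    computed for the condition's score.
    """
    if condition not in {"a", "b"}:
        raise ValueError("condition must be 'a' or 'b'")
    bound = []
    for rec in tfbs:
        p = rec.p_bound_a if condition == "a" else rec.p_bound_b
        if p is None:
            if null_scores is None:
                raise ValueError(
                    f"TFBS {rec.tfbs_id}: no bound p-value for condition {condition} "
                    "and no null sample to compute one"
                )
            p = empirical_pvalue(rec.score_a if condition == "a" else rec.score_b, null_scores)
        if p < p_threshold:
            bound.append(rec)
    return bound


def differential_binding(tfbs: Sequence[TFBSRecord]) -> np.ndarray:
    """Per-site differential binding (score_b - score_a) as an array."""
    return np.array([rec.diff for rec in tfbs], dtype=float)


def build_matrix(
    bound_tfbs: Iterable[TFBSRecord],
    signature_genes: Iterable[str],
    tfs: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x TF matrix of mean differential binding, plus per-cell counts.

    Rows are the given signature genes (one expression direction), columns TF
    names; a cell is the arithmetic mean of the differential binding of all
    bound sites of that TF annotated to that gene, and 0 when no site exists.
    Records without gene annotation are excluded (count logged). Duplicate
    footprints under several TF names contribute to each TF's cell.
    """
    genes = sorted(set(signature_genes))
    gene_set = set(genes)
    rows = []
    skipped = 0
    for rec in bound_tfbs:
        if rec.gene_id is None:
            skipped += 1
            continue
        if rec.gene_id in gene_set:
            rows.append((rec.gene_id, rec.tf, rec.diff))
    if skipped:
        logger.info("excluded %d TFBS without gene annotation", skipped)
    table = pd.DataFrame(rows, columns=["gene_id", "tf", "diff"])
    tf_index = sorted(set(table["tf"]) if tfs is None else set(tfs))
    mean = (
        table.pivot_table(index="gene_id", columns="tf", values="diff", aggfunc="mean")
        .reindex(index=genes, columns=tf_index)
        .fillna(0.0)
    )
    count = (
        table.pivot_table(index="gene_id", columns="tf", values="diff", aggfunc="size")
        .reindex(index=genes, columns=tf_index)
        .fillna(0)
        .astype(int)
    )
    return mean, count


def duplicate_fraction(tfbs: Sequence[TFBSRecord]) -> float:
    """Fraction of footprints sharing exact coordinates with a different TF.

    A footprint counts as duplicated when at least one other record of a
    *different* TF occupies the identical (chrom, start, end).
    """
    records = list(tfbs)
    if not records:
        raise ValueError("empty TFBS set")
    tfs_at: dict[tuple[str, int, int], set[str]] = {}
    for rec in records:
        tfs_at.setdefault(rec.coordinates, set()).add(rec.tf)
    n_dup = sum(1 for rec in records if len(tfs_at[rec.coordinates] - {rec.tf}) >= 1)
    return n_dup / len(records)


# ---------------------------------------------------------------------------
# TSV interchange
# ---------------------------------------------------------------------------

def read_tfbs(path) -> list[TFBSRecord]:
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    records = []
    for row in table.itertuples(index=False):
        records.append(
            TFBSRecord(
                tfbs_id=str(row.tfbs_id),
                tf=str(row.tf),
                motif_id=str(row.motif_id),
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                strand=str(row.strand),
                motif_score=float(row.motif_score),
                score_a=float(row.score_a),
                score_b=float(row.score_b),
                p_bound_a=None if pd.isna(row.p_bound_a) else float(row.p_bound_a),
                p_bound_b=None if pd.isna(row.p_bound_b) else float(row.p_bound_b),
                roc_id=None if pd.isna(row.roc_id) else str(row.roc_id),
                gene_id=None if pd.isna(row.gene_id) else str(row.gene_id),
            )
        )
    return records


def write_tfbs(path, tfbs: Sequence[TFBSRecord]) -> None:
    rows = [
        (
            r.tfbs_id, r.tf, r.motif_id, r.chrom, r.start, r.end, r.strand,
            r.motif_score, r.score_a, r.score_b, r.p_bound_a, r.p_bound_b,
            r.roc_id, r.gene_id,
        )
        for r in sorted(tfbs, key=lambda r: r.tfbs_id)
    ]
    pd.DataFrame(rows, columns=_TFBS_COLUMNS).to_csv(path, sep="\t", index=False)
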