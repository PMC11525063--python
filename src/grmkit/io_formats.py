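"""Readers and writers for the interval, gene-model, variant and table formats
used across the pipeline.

Coordinate conventions
----------------------
All internal arithmetic is 0-based half-open. BED input is already 0-based
half-open and is taken verbatim; VCF positions are 1-based and are converted
only at the I/O boundary (``VariantRecord.pos`` keeps the 1-based value,
``VariantRecord.pos0`` exposes the internal convention).

All tabular writes are tab-delimited UTF-8 with a deterministic row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "VariantRecord",
    "read_regions",
    "write_regions",
    "read_gene_models",
    "write_gene_models",
    "read_variants",
    "write_vcf",
    "read_counts",
    "write_counts",
    "read_design",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with a unique identifier."""

    chrom: str
    start: int
    end: int
    id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end} ({self.id})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GeneModel:
    """A gene span with a strand-aware transcription start site.

    The TSS is the 5' end of the span: ``start`` on the plus strand,
    ``end - 1`` on the minus strand (both 0-based).
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"unknown strand {self.strand!r} for gene {self.gene_id}")
        if self.start >= self.end:
            raise ValueError(f"empty gene span for {self.gene_id}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.gene_id)


@dataclass(frozen=True)
class VariantRecord:
    """One alternate allele of a single-nucleotide variant.

    Multi-allelic VCF rows are split into one record per alt allele.
    ``af_nfe`` is ``None`` when the population frequency is not annotated
    (missing, not zero). ``carriers`` holds the sample ids with at least one
    copy of this alt allele.
    """

    chrom: str
    pos: int  # 1-based, as in the VCF
    ref: str
    alt: str
    af_nfe: Optional[float]
    consequence: str
    depth: int
    carriers: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"VCF position must be >= 1, got {self.pos}")
        if self.depth < 0:
            raise ValueError(f"negative depth {self.depth} at {self.chrom}:{self.pos}")
        if self.af_nfe is not None and not (0.0 <= self.af_nfe <= 1.0):
            raise ValueError(f"AF_NFE {self.af_nfe} outside [0,1] at {self.chrom}:{self.pos}")

    @property
    def pos0(self) -> int:
        """0-based position (internal convention)."""
        return self.pos - 1


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_regions(path) -> list[GenomicInterval]:
    """Read a 3+ column BED file into intervals (file order preserved).

    The 4th column is used as the interval id when present; otherwise ids
    ``peak_1``, ``peak_2``, ... are assigned in file order.
    """
    intervals: list[GenomicInterval] = []
    n_records = 0
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            n_records += 1
            name = fields[3] if len(fields) >= 4 and fields[3] not in {"", "."} else f"peak_{n_records}"
            if start >= end:
                raise ValueError(
                    f"{path}: line {lineno}: start {start} >= end {end} (BED is half-open)"
                )
            intervals.append(GenomicInterval(chrom, start, end, name))
    return intervals


def write_regions(path, intervals: Iterable[GenomicInterval]) -> None:
    """Write intervals as 4-column BED, in the given order."""
    with open(path, "w", encoding="utf-8") as handle:
        for iv in intervals:
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\n")


# ---------------------------------------------------------------------------
# Gene models (GTF-lite TSV)
# ---------------------------------------------------------------------------

_GENE_COLUMNS = ["gene_id", "chrom", "strand", "start", "end"]


def read_gene_models(path) -> list[GeneModel]:
    """Read gene models from a headered TSV (gene_id, chrom, strand, start, end)."""
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    missing = [c for c in _GENE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    dupes = table["gene_id"][table["gene_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate gene_id values {sorted(set(dupes))}")
    return [
        GeneModel(row.gene_id, row.chrom, row.strand, int(row.start), int(row.end))
        for row in table.itertuples(index=False)
    ]


def write_gene_models(path, genes: Sequence[GeneModel]) -> None:
    table = pd.DataFrame(
        [(g.gene_id, g.chrom, g.strand, g.start, g.end) for g in genes],
        columns=_GENE_COLUMNS,
    )
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _per_alt(value, n_alt: int, index: int):
    """Pick the value for alt allele ``index`` from a scalar or per-alt tuple."""
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        return value[index] if index < len(value) else None
    if isinstance(value, str) and n_alt > 1 and "," in value:
        parts = value.split(",")
        return parts[index] if index < len(parts) else None
    return value


def read_variants(path) -> list[VariantRecord]:
    """Read a VCF 4.x file into variant records, one per alt allele.

    Expects INFO keys ``AF_NFE`` (may be absent per record), ``CSQ`` (a
    consequence label) and ``DP``, plus per-sample GT fields. Carriers are the
    samples whose genotype contains the record's alt allele at least once.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no sample/GT columns")
    records: list[VariantRecord] = []
    for var in vcf:
        dp = var.INFO.get("DP")
        if dp is None:
            raise ValueError(f"{path}: missing DP at {var.CHROM}:{var.POS}")
        try:
            depth = int(dp)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: non-numeric DP {dp!r} at {var.CHROM}:{var.POS}") from exc
        af = var.INFO.get("AF_NFE")
        csq = var.INFO.get("CSQ")
        try:
            genotypes = var.genotypes
        except Exception as exc:  # cyvcf2 raises when FORMAT lacks GT
            raise ValueError(f"{path}: missing GT at {var.CHROM}:{var.POS}") from exc
        n_alt = len(var.ALT)
        for i, alt in enumerate(var.ALT):
            allele = i + 1
            carriers = frozenset(
                s for s, gt in zip(samples, genotypes) if allele in gt[:-1]
            )
            af_i = _per_alt(af, n_alt, i)
            csq_i = _per_alt(csq, n_alt, i)
            records.append(
                VariantRecord(
                    chrom=var.CHROM,
                    pos=var.POS,
                    ref=var.REF,
                    alt=alt,
                    # htslib parses floats at single precision; 6 significant
                    # digits recovers the printed value
                    af_nfe=None if af_i is None else float(f"{float(af_i):.6g}"),
                    consequence=str(csq_i) if csq_i is not None else "unknown",
                    depth=depth,
                    carriers=carriers,
                )
            )
    return records


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##INFO=<ID=AF_NFE,Number=1,Type=Float,Description="Allele frequency, non-Finnish Europeans">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence label">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(path, records: Sequence[VariantRecord], samples: Sequence[str]) -> None:
    """Write variant records as an uncompressed VCF 4.2 with GT per sample.

    Records are emitted sorted by (chrom, pos, ref, alt) so identical inputs
    produce byte-identical files. Carriers get genotype 0/1; everyone else 0/0.
    """
    ordered = sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(_VCF_HEADER)
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for rec in ordered:
            info = [f"DP={rec.depth}"]
            if rec.af_nfe is not None:
                info.append(f"AF_NFE={rec.af_nfe:.6g}")
            info.append(f"CSQ={rec.consequence}")
            gts = "\t".join("0/1" if s in rec.carriers else "0/0" for s in samples)
            handle.write(
                f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t"
                + ";".join(info)
                + f"\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Count matrices and designs
# ---------------------------------------------------------------------------

def read_counts(path) -> pd.DataFrame:
    """Read a features x samples count TSV; first column is the feature id."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if (counts.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative counts")
    return counts


def write_counts(path, counts: pd.DataFrame) -> None:
    counts.to_csv(path, sep="\t")


def read_design(path) -> pd.Series:
    """Read a 2-column sample/group TSV into a sample -> group Series."""
    design = pd.read_csv(path, sep="\t", dtype=str)
    if design.shape[1] < 2:
        raise ValueError(f"{path}: expected columns sample, group")
    return pd.Series(design.iloc[:, 1].values, index=design.iloc[:, 0].values, name="group")
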