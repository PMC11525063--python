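"""Independent brute-force oracles used to cross-check the library.

Every function here is written as the most literal possible implementation
(loops, full scans) and never shares code with the package.
"""

from __future__ import annotations

import numpy as np


def bh_stepup(p_values) -> np.ndarray:
    """BH adjusted p: q_i = min_{j: p_j >= p_i ranked} (p_(j) * n / j), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(n)
    running_min = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * n / rank)
        adjusted[idx] = running_min
    return adjusted


def group_mean_matrix(records, genes, tfs):
    """Mean diff per (gene, TF) by explicit double loop; 0 when no record."""
    mean = np.zeros((len(genes), len(tfs)))
    count = np.zeros((len(genes), len(tfs)), dtype=int)
    for gi, g in enumerate(genes):
        for ti, t in enumerate(tfs):
            diffs = [r.diff for r in records if r.gene_id == g and r.tf == t]
            if diffs:
                mean[gi, ti] = sum(diffs) / len(diffs)
                count[gi, ti] = len(diffs)
    return mean, count


def submatrix_density(matrix, genes, tfs) -> float:
    """Sum of cells over |G| x |T|, by explicit loops."""
    total = 0.0
    for g in genes:
        for t in tfs:
            total += matrix.loc[g, t]
    return total / (len(genes) * len(tfs))


def nearest_tss_scan(rocs, gene_models):
    """All-pairs nearest-TSS assignment; ties to the smaller gene id."""
    out = {}
    for roc in rocs:
        best = None
        mid = (roc.start + roc.end) // 2
        for gene in gene_models:
            if gene.chrom != roc.chrom:
                continue
            d = abs(mid - gene.tss)
            if best is None or d < best[0] or (d == best[0] and gene.gene_id < best[1]):
                best = (d, gene.gene_id)
        if best is not None:
            out[roc.id] = best[1]
    return out


def burden_scan(variants, loci, individuals):
    """Per-individual (fraction mutated, SNV/100kb) by full scans."""
    total_len = sum(l.total_length for l in loci)
    out = {}
    for person in individuals:
        genes_hit = set()
        n_snv = 0
        for var in variants:
            if person not in var.carriers:
                continue
            for locus in loci:
                if locus.chrom != var.chrom:
                    continue
                inside = any(s <= var.pos - 1 < e for s, e in locus.intervals)
                if inside:
                    genes_hit.add(locus.gene_id)
                    n_snv += 1
        out[person] = (len(genes_hit) / len(loci), 1e5 * n_snv / total_len)
    return out


def ffl_triples(binds: dict, focal: str, tf_gene_map: dict):
    """Feed-forward loops by explicit triple enumeration.

    ``binds`` maps TF -> set of target genes.
    """
    loops = set()
    for intermediate, inter_gene in tf_gene_map.items():
        if intermediate == focal:
            continue
        for target in binds.get(intermediate, set()):
            if inter_gene in binds.get(focal, set()) and target in binds.get(focal, set()):
                loops.add((focal, intermediate, target))
    return loops


def tmm_recipe(counts, ref_sample, trim_m=0.30, trim_a=0.05):
    """The TMM factor recipe, re-implemented with plain loops over samples."""
    lib = {s: float(counts[s].sum()) for s in counts.columns}
    ref = counts[ref_sample].to_numpy(dtype=float)
    raw = {}
    for sample in counts.columns:
        obs = counts[sample].to_numpy(dtype=float)
        m_vals, a_vals, weights = [], [], []
        for o, r in zip(obs, ref):
            if o > 0 and r > 0:
                x = o / lib[sample]
                y = r / lib[ref_sample]
                m_vals.append(np.log2(x / y))
                a_vals.append(0.5 * np.log2(x * y))
                weights.append(
                    1.0
                    / (
                        (lib[sample] - o) / (lib[sample] * o)
                        + (lib[ref_sample] - r) / (lib[ref_sample] * r)
                    )
                )
        m_vals, a_vals, weights = map(np.array, (m_vals, a_vals, weights))
        keep = (
            (m_vals >= np.quantile(m_vals, trim_m))
            & (m_vals <= np.quantile(m_vals, 1 - trim_m))
            & (a_vals >= np.quantile(a_vals, trim_a))
            & (a_vals <= np.quantile(a_vals, 1 - trim_a))
        )
        raw[sample] = 2 ** (np.sum(weights[keep] * m_vals[keep]) / np.sum(weights[keep]))
    log_factors = np.log([raw[s] for s in counts.columns])
    gm = np.exp(log_factors.mean())
    return {s: raw[s] / gm for s in counts.columns}
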