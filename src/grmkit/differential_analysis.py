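"""Two-group differential testing shared by expression (DEG) and chromatin
accessibility (DCA) contrasts.

The pipeline is the classic count-based recipe: counts-per-million (CPM)
conversion, low-signal filtering, trimmed-mean-of-M-values (TMM) scaling,
a per-feature two-sided Welch t test on TMM-scaled log2-CPM, and
Benjamini-Hochberg FDR control, followed by thresholded signature selection
(|log2FC| >= threshold and FDR < alpha).

Two per-feature statistics are available. The default, a moderated t,
shrinks per-feature pooled variances toward a common prior fitted by the
classic scaled-inverse-chi-square empirical-Bayes recipe before forming the
t statistic — essential at two or three replicates per group, where raw
variance estimates are too noisy to rank features reliably. A plain Welch t
(``statistic="welch"``) is kept as the unmoderated reference. See
docs/methods.md for the trade-offs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Signature",
    "cpm",
    "filter_low",
    "tmm_factors",
    "log_cpm",
    "bh_adjust",
    "squeeze_variances",
    "differential_test",
    "select_signature",
]


@dataclass(frozen=True)
class Signature:
    """Up- and down-regulated feature sets from a thresholded contrast."""

    up: frozenset
    down: frozenset

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down signature sets overlap")

    @property
    def genes(self) -> frozenset:
        return self.up | self.down


def _library_sizes(counts: pd.DataFrame) -> pd.Series:
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"zero library size for samples {bad}")
    return lib


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: count * 1e6 / column library size."""
    lib = _library_sizes(counts)
    return counts * 1e6 / lib


def filter_low(counts: pd.DataFrame, min_cpm: float = 1.0, max_below: int = 2) -> pd.DataFrame:
    """Drop features with CPM < ``min_cpm`` in more than ``max_below`` samples.

    A feature is kept iff the number of samples below the CPM floor is at most
    ``max_below``; row order is preserved.
    """
    if min_cpm < 0 or max_below < 0:
        raise ValueError("thresholds must be non-negative")
    below = (cpm(counts) < min_cpm).sum(axis=1)
    return counts.loc[below <= max_below]


def tmm_factors(
    counts: pd.DataFrame,
    ref_sample: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    Reference sample: the one whose upper-quartile of count fractions is
    closest to the mean upper-quartile (unless given). Per sample, M and A
    values are computed over features positive in both sample and reference;
    M is trimmed to its [trim_m, 1-trim_m] quantile range and A to
    [trim_a, 1-trim_a]; the factor is 2**(inverse-variance weighted mean of
    the retained M), using the delta-method weights of the TMM recipe.
    """
    lib = _library_sizes(counts)
    frac = counts / lib
    if ref_sample is None:
        uq = frac.quantile(0.75)
        ref_sample = (uq - uq.mean()).abs().idxmin()
    ref = counts[ref_sample].to_numpy(dtype=float)
    nr = float(lib[ref_sample])

    factors = {}
    for sample in counts.columns:
        obs = counts[sample].to_numpy(dtype=float)
        ns = float(lib[sample])
        pos = (obs > 0) & (ref > 0)
        if not pos.any():
            raise ValueError(f"sample {sample} shares no positive features with reference")
        x, r = obs[pos] / ns, ref[pos] / nr
        m = np.log2(x / r)
        a = 0.5 * np.log2(x * r)
        keep = (
            (m >= np.quantile(m, trim_m))
            & (m <= np.quantile(m, 1 - trim_m))
            & (a >= np.quantile(a, trim_a))
            & (a <= np.quantile(a, 1 - trim_a))
        )
        if not keep.any():
            keep = np.ones_like(m, dtype=bool)
        w = 1.0 / ((ns - obs[pos]) / (ns * obs[pos]) + (nr - ref[pos]) / (nr * ref[pos]))
        factors[sample] = 2 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))

    out = pd.Series(factors, index=counts.columns, dtype=float)
    return out / np.exp(np.log(out).mean())


def log_cpm(counts: pd.DataFrame, factors: pd.Series | None = None, offset: float = 0.5) -> pd.DataFrame:
    """log2 CPM with a count offset, on TMM-effective library sizes."""
    lib = _library_sizes(counts)
    if factors is not None:
        lib = lib * factors
    return np.log2((counts + offset) * 1e6 / lib)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    from scipy.special import polygamma

    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        f = float(polygamma(1, x)) - y
        step = f / float(polygamma(2, x))
        x = max(x - step, 1e-8)
        if abs(step) < tol * x:
            break
    return x


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of per-feature variances.

    Fits a scaled inverse chi-square prior (d0, s0^2) to the observed sample
    variances by matching the moments of log s^2, then returns the posterior
    variances (d0*s0^2 + df*s2) / (d0 + df) together with the fitted prior.
    An infinite d0 (variances more concordant than chi-square sampling noise
    allows) collapses every variance to the common value.
    """
    from scipy.special import digamma, polygamma

    s2 = np.asarray(s2, dtype=float)
    positive = s2 > 0
    if positive.sum() < 2:
        raise ValueError("need >=2 positive variances to fit the prior")
    z = np.log(s2[positive])
    e = z - float(digamma(df / 2)) + np.log(df / 2)
    e_var = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2))
    if e_var <= 0:
        # variances more concordant than chi-square noise allows: common value
        d0, s0_sq = np.inf, float(np.mean(s2[positive]))
        post = np.full_like(s2, s0_sq)
    else:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = float(np.exp(e.mean() + digamma(d0 / 2) - np.log(d0 / 2)))
        post = (d0 * s0_sq + df * s2) / (d0 + df)
    return post, d0, s0_sq


def differential_test(
    counts: pd.DataFrame,
    groups: pd.Series,
    factors: pd.Series | None = None,
    offset: float = 0.5,
    statistic: str = "moderated",
) -> pd.DataFrame:
    """Per-feature two-group contrast (B vs A) on TMM-scaled log2-CPM.

    ``groups`` maps sample id -> label; the lexicographically smaller label is
    treated as the baseline A. ``statistic`` chooses between the moderated t
    (pooled variances shrunk toward an empirical-Bayes prior; p from a t
    distribution with prior + residual degrees of freedom) and a plain Welch
    t. Returns a DataFrame indexed by feature id with columns log2fc,
    mean_logcpm, p_raw, fdr. Features with zero variance in both groups get
    p = 1 when the group means are equal (and p = 0 under Welch when they are
    not, since the difference is then noiseless).
    """
    groups = pd.Series(groups)
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"expected exactly two groups, got {labels}")
    a_samples = groups.index[groups == labels[0]]
    b_samples = groups.index[groups == labels[1]]
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise ValueError("need >=2 samples per group")

    logc = log_cpm(counts, factors=factors, offset=offset)
    la = logc[a_samples].to_numpy()
    lb = logc[b_samples].to_numpy()
    na, nb = la.shape[1], lb.shape[1]
    log2fc = lb.mean(axis=1) - la.mean(axis=1)
    if statistic == "welch":
        import warnings

        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p_raw = stats.ttest_ind(lb, la, axis=1, equal_var=False).pvalue
        degenerate = ~np.isfinite(p_raw)
        p_raw = np.where(degenerate, np.where(np.isclose(log2fc, 0.0), 1.0, 0.0), p_raw)
    elif statistic == "moderated":
        df_resid = na + nb - 2
        s2 = (la.var(axis=1, ddof=1) * (na - 1) + lb.var(axis=1, ddof=1) * (nb - 1)) / df_resid
        post_var, d0, _ = squeeze_variances(s2, df_resid)
        se = np.sqrt(post_var * (1.0 / na + 1.0 / nb))
        with np.errstate(invalid="ignore", divide="ignore"):
            t = log2fc / se
        df_total = d0 + df_resid
        if np.isfinite(df_total):
            p_raw = 2 * stats.t.sf(np.abs(t), df_total)
        else:
            p_raw = 2 * stats.norm.sf(np.abs(t))
        p_raw = np.where(np.isfinite(p_raw), p_raw, 1.0)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "mean_logcpm": logc.to_numpy().mean(axis=1),
            "p_raw": p_raw,
            "fdr": bh_adjust(p_raw),
        },
        index=counts.index.rename("feature_id"),
    )


def select_signature(results: pd.DataFrame, lfc_threshold: float = 1.0, alpha: float = 0.05) -> Signature:
    """Thresholded signature: |log2fc| >= threshold (closed) and fdr < alpha (open)."""
    sig = results["fdr"] < alpha
    up = results.index[sig & (results["log2fc"] >= lfc_threshold)]
    down = results.index[sig & (results["log2fc"] <= -lfc_threshold)]
    return Signature(up=frozenset(up), down=frozenset(down))
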