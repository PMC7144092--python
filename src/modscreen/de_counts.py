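"""Simplified count-based differential expression and GO over-representation.

The stage mirrors the standard RNA-seq workflow — median-of-ratios
normalization, a per-gene negative-binomial two-group test, BH adjustment,
and hypergeometric category enrichment — but deliberately without dispersion
shrinkage, fold-change moderation or independent filtering.  It is meant for
calibrated analysis of synthetic count matrices where the ground truth is
known, not as a drop-in for a production DE tool.

Model: counts ``K_gj ~ NB(mean = s_j * q_gc, dispersion alpha_g)`` with
sample size factor ``s_j``, condition mean ``q_gc`` and gene dispersion
``alpha_g`` (Var = mu + alpha * mu^2).  The test statistic is a Wald ratio
of the log2 fold change of normalized condition means to its delta-method
standard error, referred to a t distribution with n_A + n_B - 2 degrees of
freedom (the normal reference is visibly anti-conservative at 4 vs 4
replicates; see docs/methods.md).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .core_stats import bh_adjust

__all__ = [
    "size_factors",
    "normalized_counts",
    "nb_test",
    "de_set",
    "go_overrep",
]

LFC_PSEUDOCOUNT = 0.5  # normalized units added to condition means
DISPERSION_FLOOR = 1e-8


def _as_counts(counts: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(counts, pd.DataFrame):
        raise TypeError("counts must be a genes x samples DataFrame")
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    values = counts.to_numpy()
    if np.any(values < 0):
        raise ValueError("counts must be non-negative")
    return counts


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each gene with a positive geometric mean across samples, form the
    ratio count / geometric mean; a sample's size factor is the median of
    its ratios.  Genes with any zero count are excluded (their geometric
    mean is zero).
    """
    counts = _as_counts(counts)
    values = counts.to_numpy(dtype=float)
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in every sample")
    log_values = np.log(values[positive])
    log_geomean = log_values.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_values - log_geomean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalized_counts(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts divided by their sample size factors."""
    counts = _as_counts(counts)
    if factors is None:
        factors = size_factors(counts)
    return counts / factors


def _condition_samples(design: pd.DataFrame, condition: str) -> list[str]:
    if not {"sample", "condition"} <= set(design.columns):
        raise ValueError("design needs 'sample' and 'condition' columns")
    samples = design.loc[design["condition"] == condition, "sample"].tolist()
    if len(samples) < 2:
        raise ValueError(f"condition {condition!r} needs >= 2 replicates, found {len(samples)}")
    return samples


def nb_test(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    *,
    epsilon: float = LFC_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene negative-binomial Wald test of condition B vs condition A.

    Returns a DataFrame indexed by gene with columns ``base_mean_a``,
    ``base_mean_b`` (normalized condition means), ``log2_fold_change``
    (of B over A, with pseudo-count ``epsilon``), ``lfc_uses_pseudocount``
    (True when either raw mean is zero), ``dispersion`` (pooled
    method-of-moments estimate, floored), ``se``, ``stat``, ``p_value``
    and ``p_adj`` (BH over all tested genes).  Genes with zero counts in
    every sample are dropped before testing.
    """
    counts = _as_counts(counts)
    samples_a = _condition_samples(design, cond_a)
    samples_b = _condition_samples(design, cond_b)
    missing = (set(samples_a) | set(samples_b)) - set(counts.columns)
    if missing:
        raise ValueError(f"design samples missing from counts: {sorted(missing)}")

    sub = counts[samples_a + samples_b]
    expressed = sub.to_numpy().sum(axis=1) > 0
    sub = sub.loc[expressed]
    factors = size_factors(sub)
    norm = sub.to_numpy(dtype=float) / factors.to_numpy()

    n_a, n_b = len(samples_a), len(samples_b)
    norm_a, norm_b = norm[:, :n_a], norm[:, n_a:]
    mean_a, mean_b = norm_a.mean(axis=1), norm_b.mean(axis=1)

    # Method-of-moments dispersion per condition (Var = mu/s + alpha mu^2 on
    # normalized counts), pooled across the two conditions with df weights.
    inv_s_a = float(np.mean(1.0 / factors.to_numpy()[:n_a]))
    inv_s_b = float(np.mean(1.0 / factors.to_numpy()[n_a:]))
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_a = (norm_a.var(axis=1, ddof=1) - mean_a * inv_s_a) / mean_a**2
        disp_b = (norm_b.var(axis=1, ddof=1) - mean_b * inv_s_b) / mean_b**2
    weights_a = np.where(np.isfinite(disp_a), n_a - 1.0, 0.0)
    weights_b = np.where(np.isfinite(disp_b), n_b - 1.0, 0.0)
    total_w = weights_a + weights_b
    dispersion = (
        np.nan_to_num(disp_a, nan=0.0, posinf=0.0, neginf=0.0) * weights_a
        + np.nan_to_num(disp_b, nan=0.0, posinf=0.0, neginf=0.0) * weights_b
    ) / np.where(total_w > 0, total_w, 1.0)
    dispersion = np.maximum(dispersion, DISPERSION_FLOOR)

    lfc = np.log2(mean_b + epsilon) - np.log2(mean_a + epsilon)
    # Var of a condition mean of normalized counts under the NB model,
    # then delta method through log2(mean + eps).
    var_mean_a = (mean_a * inv_s_a + dispersion * mean_a**2) / n_a
    var_mean_b = (mean_b * inv_s_b + dispersion * mean_b**2) / n_b
    ln2 = np.log(2.0)
    se2 = var_mean_a / ((mean_a + epsilon) ** 2) + var_mean_b / ((mean_b + epsilon) ** 2)
    se = np.sqrt(se2) / ln2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, lfc / se, 0.0)
    df = n_a + n_b - 2
    p = 2.0 * _stats.t.sf(np.abs(stat), df)
    p = np.minimum(p, 1.0)

    out = pd.DataFrame(
        {
            "base_mean_a": mean_a,
            "base_mean_b": mean_b,
            "log2_fold_change": lfc,
            "lfc_uses_pseudocount": (mean_a == 0) | (mean_b == 0),
            "dispersion": dispersion,
            "se": se,
            "stat": stat,
            "p_value": p,
        },
        index=sub.index,
    )
    out["p_adj"] = bh_adjust(out["p_value"].to_numpy())
    out.attrs["conditions"] = (cond_a, cond_b)
    out.attrs["size_factors"] = factors
    return out


def de_set(
    results: pd.DataFrame,
    *,
    padj_threshold: float = 0.05,
    fc_threshold: float | None = None,
) -> tuple[list, list]:
    """(up-regulated, down-regulated) gene lists at ``p_adj < padj_threshold``,
    optionally also requiring |fold change| > ``fc_threshold`` (on the linear
    scale, e.g. 2 for two-fold)."""
    if results.empty:
        return [], []
    hits = results[results["p_adj"] < padj_threshold]
    if fc_threshold is not None:
        if fc_threshold <= 0:
            raise ValueError("fc_threshold must be positive")
        hits = hits[np.abs(hits["log2_fold_change"]) > np.log2(fc_threshold)]
    up = hits.index[hits["log2_fold_change"] > 0].tolist()
    down = hits.index[hits["log2_fold_change"] < 0].tolist()
    return up, down


def go_overrep(
    de_genes,
    universe,
    term_map: dict[str, set],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of each term's gene set
    within the DE list, BH-adjusted across terms.

    ``de_genes`` must be a subset of ``universe``; every term's gene set is
    intersected with the universe before testing.
    """
    de = set(de_genes)
    uni = set(universe)
    if not de <= uni:
        raise ValueError(f"DE genes outside the universe: {sorted(de - uni)[:5]}")
    n_uni, n_de = len(uni), len(de)
    rows = []
    for term, genes in term_map.items():
        members = set(genes) & uni
        overlap = len(members & de)
        # P(X >= overlap) for X ~ Hypergeom(N=n_uni, K=len(members), n=n_de)
        p = float(_stats.hypergeom.sf(overlap - 1, n_uni, len(members), n_de))
        rows.append((term, len(members), overlap, min(1.0, p)))
    out = pd.DataFrame(rows, columns=["term", "term_size", "overlap", "p_value"]).set_index("term")
    if len(out):
        out["p_adj"] = bh_adjust(out["p_value"].to_numpy())
    return out
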