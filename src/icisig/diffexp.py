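"""Two-group negative-binomial differential expression on raw counts.

The stage mirrors the classical bulk RNA-seq workflow: per-sample size
factors by the median-of-ratios method, a per-gene negative-binomial Wald
test of the responder vs non-responder mean contrast, Benjamini-Hochberg
multiple-testing correction, and selection of differentially expressed
genes at FDR < 0.05 with fold change > 2.

The Wald test here is deliberately simple and fully documented rather than
a port of a shrinkage-based DE engine: per-gene dispersion is estimated by
the method of moments on size-factor-normalized counts (pooled within-group
variance), floored at 1e-8, and the log2 fold change uses a pseudocount of
0.5 normalized counts so that zero-mean groups stay finite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import ExpressionMatrix

#: pseudocount (normalized counts) added to group means before the log2 ratio
LOG2FC_PSEUDOCOUNT = 0.5
#: lower bound for the method-of-moments dispersion estimate
DISPERSION_FLOOR = 1e-8

__all__ = [
    "estimate_size_factors",
    "nb_two_group_test",
    "bh_adjust",
    "select_degs",
    "write_de_results",
]


def estimate_size_factors(counts: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Reference genes are the rows with strictly positive counts in every
    sample; each sample's factor is the median over reference genes of the
    ratio of its count to the gene's geometric mean.
    """
    if counts.value_kind != "counts":
        raise ValueError("size factors are estimated from raw counts")
    values = counts.values
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in all samples; "
            "filter lower-depth samples or add a pseudocount upstream"
        )
    ref = values[positive]
    log_geo_mean = np.log(ref).mean(axis=1)
    ratios = np.exp(np.log(ref) - log_geo_mean[:, None])
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.log(factors).mean())  # geometric mean 1
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def _group_columns(
    counts: ExpressionMatrix, labels: pd.Series | dict, group_a: str, group_b: str
) -> tuple[np.ndarray, np.ndarray]:
    labels = pd.Series(labels)
    cols = pd.Index(counts.sample_ids)
    a = np.asarray([s in labels.index and labels[s] == group_a for s in cols])
    b = np.asarray([s in labels.index and labels[s] == group_b for s in cols])
    if a.sum() < 2 or b.sum() < 2:
        raise ValueError(
            f"each group needs >= 2 samples; got {group_a}={a.sum()}, "
            f"{group_b}={b.sum()}"
        )
    return a, b


def nb_two_group_test(
    counts: ExpressionMatrix,
    labels: pd.Series | dict,
    size_factors: pd.Series | None = None,
    group_a: str = "DR",
    group_b: str = "NR",
) -> pd.DataFrame:
    """Per-gene NB Wald test of ``group_a`` (responders) vs ``group_b``.

    Parameters
    ----------
    counts:
        Raw counts, genes x samples.
    labels:
        Sample id -> group label; samples outside the two groups are ignored.
    size_factors:
        Per-sample normalization factors; estimated if not supplied.

    Returns
    -------
    DataFrame indexed by gene with columns ``mean_expression`` (overall mean
    of normalized counts), ``log2fc`` (positive = higher in ``group_a``),
    ``p_value`` and ``q_value`` (BH).

    Notes
    -----
    Normalized counts k/sf are treated per gene as draws with mean mu and
    NB variance mu + alpha*mu^2.  The dispersion alpha is the pooled
    within-group method-of-moments estimate.  The Wald statistic contrasts
    log group means via the delta method and is referred to a t distribution
    with n_a + n_b - 2 degrees of freedom (two-sided), a small-sample
    correction for the moment-based variance estimate.
    """
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    sf = size_factors.loc[counts.sample_ids].to_numpy(dtype=float)
    if (sf <= 0).any():
        raise ValueError("size factors must be positive")
    in_a, in_b = _group_columns(counts, labels, group_a, group_b)
    norm = counts.values / sf[None, :]
    xa, xb = norm[:, in_a], norm[:, in_b]
    na, nb = xa.shape[1], xb.shape[1]

    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    va, vb = xa.var(axis=1, ddof=1), xb.var(axis=1, ddof=1)
    mu = norm[:, in_a | in_b].mean(axis=1)
    pooled_var = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - mu) / np.square(mu)
    alpha = np.where(np.isfinite(alpha), alpha, 0.0)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)

    c = LOG2FC_PSEUDOCOUNT
    log2fc = np.log2((ma + c) / (mb + c))
    # delta-method variance of ln(mean + c) under NB sampling of the group mean
    var_ma = (ma + alpha * ma**2) / na
    var_mb = (mb + alpha * mb**2) / nb
    se_ln = np.sqrt(var_ma / np.square(ma + c) + var_mb / np.square(mb + c))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.log(2) * log2fc / se_ln
    df = na + nb - 2
    p = 2.0 * stats.t.sf(np.abs(z), df)

    all_zero = (ma == 0) & (mb == 0)
    p = np.where(all_zero, 1.0, p)
    log2fc = np.where(all_zero, 0.0, log2fc)
    p = np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)

    out = pd.DataFrame(
        {
            "mean_expression": mu,
            "log2fc": log2fc,
            "p_value": p,
            "all_zero": all_zero,
        },
        index=pd.Index(counts.gene_ids, name="gene_id"),
    )
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out[["mean_expression", "log2fc", "p_value", "q_value", "all_zero"]]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} m * p_(j) / j over the sorted p-values, capped at 1,
    returned in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def select_degs(
    results: pd.DataFrame, max_fdr: float = 0.05, min_abs_log2fc: float = 1.0
) -> list[str]:
    """Genes with q < ``max_fdr`` and |log2fc| strictly above ``min_abs_log2fc``.

    The defaults encode FDR < 0.05 with fold change > 2.
    """
    mask = (results["q_value"] < max_fdr) & (
        results["log2fc"].abs() > min_abs_log2fc
    )
    return list(results.index[mask])


def write_de_results(results: pd.DataFrame, path) -> None:
    """Write DE results as TSV: gene_id, mean_expression, log2fc, p_value, q_value."""
    cols = ["mean_expression", "log2fc", "p_value", "q_value"]
    results[cols].to_csv(path, sep="\t", index_label="gene_id")
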