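"""Correlation-to-steady-state profiling and time-course differential
expression.

The correlation profile condenses each sample into one number: the Pearson
correlation of the whole transcriptome at that sample against the
pre-impulse steady state.  A perturbation shows up as a dip that recovers as
the culture re-equilibrates.

Differential expression over time is tested per gene with an F-type
statistic comparing a natural cubic spline fit of expression on
(log-warped) time against the constant model; significance comes from
permutation of the sample columns with a null distribution pooled over
genes, followed by Bonferroni and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import ExpressionSeries

__all__ = [
    "ConstantProfileError",
    "pearson",
    "correlation_profile",
    "natural_spline_basis",
    "within_class_test",
]


class ConstantProfileError(ValueError):
    """Pearson correlation is undefined for a constant vector."""


def pearson(x, y) -> float:
    """Pearson product-moment correlation of two equal-length vectors.

    Raises :class:`ConstantProfileError` (rather than silently returning 0
    or NaN) when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantProfileError("correlation undefined for a constant vector")
    r = stats.pearsonr(x, y).statistic
    return float(np.clip(r, -1.0, 1.0))


def correlation_profile(expr: ExpressionSeries) -> pd.DataFrame:
    """Transcriptome-wide Pearson correlation of every sample against the
    reference steady state.

    Returns a DataFrame with columns ``label, time_s, pcc``; the entry at
    the reference sample is exactly 1.
    """
    ref = expr.values[:, expr.grid.reference_index]
    rows = []
    for j, label in enumerate(expr.grid.labels):
        try:
            r = pearson(expr.values[:, j], ref)
        except ConstantProfileError as exc:
            raise ConstantProfileError(f"sample {label!r}: {exc}") from None
        rows.append((label, expr.grid.times[j], r))
    return pd.DataFrame(rows, columns=["label", "time_s", "pcc"])


def natural_spline_basis(x, df: int) -> np.ndarray:
    """Natural cubic spline basis (without intercept) with ``df`` columns.

    Knots are placed at ``df + 1`` quantiles of ``x``.  The basis is linear
    beyond the boundary knots (the natural constraint), built from the
    truncated power representation.
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    knots = np.quantile(x, np.linspace(0.0, 1.0, df + 1))
    knots = np.unique(knots)
    if len(knots) < df + 1:
        raise ValueError("too few distinct values in x for the requested df")
    K = len(knots)

    def d(k: int) -> np.ndarray:
        num = np.clip(x - knots[k], 0, None) ** 3 - np.clip(x - knots[K - 1], 0, None) ** 3
        return num / (knots[K - 1] - knots[k])

    cols = [x]
    d_last = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - d_last)
    basis = np.column_stack(cols)
    # centre and scale columns for numerical conditioning (does not change
    # the fitted subspace, hence not the F statistic)
    basis -= basis.mean(axis=0)
    scale = basis.std(axis=0)
    scale[scale == 0] = 1.0
    return basis / scale


def _warp_time(times_s: np.ndarray) -> np.ndarray:
    """log1p warp of post-impulse seconds; pre-impulse samples map to 0.

    The grid spans three orders of magnitude (seconds to hours), so spline
    knots on linear time would starve the sub-minute samples.
    """
    return np.log1p(np.clip(np.asarray(times_s, dtype=float), 0.0, None))


def _fstat(values: np.ndarray, basis_q: np.ndarray, df1: int) -> np.ndarray:
    """Vectorized spline-vs-constant F statistic for every gene (row).

    ``basis_q`` is an orthonormal basis (thin Q) of the centred spline
    columns; with Y centred per gene, RSS_null = ||Y||^2 and
    RSS_full = ||Y||^2 - ||Y Q||^2.
    """
    n = values.shape[1]
    yc = values - values.mean(axis=1, keepdims=True)
    tss = np.einsum("ij,ij->i", yc, yc)
    fit = yc @ basis_q
    ess = np.einsum("ij,ij->i", fit, fit)
    rss = np.maximum(tss - ess, 0.0)
    df2 = n - df1 - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ess / df1) / (rss / df2)
    f[~np.isfinite(f)] = 0.0  # constant genes and perfect fits degenerate to 0 / inf
    # perfect fits (rss == 0 with signal) deserve +inf, keep them large
    f[(rss <= 1e-12 * np.maximum(tss, 1e-300)) & (tss > 0)] = np.inf
    return f


def within_class_test(
    expr: ExpressionSeries,
    df_spline: int = 4,
    n_perm: int = 2000,
    seed: int = 0,
    alpha: float = 1e-3,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Per-gene test for any change of expression over the time course.

    A natural cubic spline with ``df_spline`` degrees of freedom is fitted
    on log-warped time and compared to the constant model with an F-type
    statistic.  Raw p-values come from ``n_perm`` permutations of the sample
    columns, pooling the permuted statistics of all genes into one null
    distribution (valid because all genes share the design and the null is
    exchangeability of columns).  The returned DataFrame has columns
    ``gene_id, stat, p, p_bonferroni, q_bh, significant``; the flag applies
    ``alpha`` to the column chosen by ``correction`` in
    {"bonferroni", "bh", "raw"}.
    """
    n = len(expr.grid)
    if n < 6:
        raise ValueError("within-class testing needs at least 6 time points")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if df_spline >= n:
        raise ValueError("df_spline must be smaller than the number of time points")
    if correction not in ("bonferroni", "bh", "raw"):
        raise ValueError("correction must be 'bonferroni', 'bh' or 'raw'")

    u = _warp_time(expr.grid.times)
    basis = natural_spline_basis(u, df_spline)
    q_obs, _ = np.linalg.qr(basis)
    f_obs = _fstat(expr.values, q_obs, df_spline)

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, expr.n_genes))
    for b in range(n_perm):
        perm = rng.permutation(n)
        qb, _ = np.linalg.qr(basis[perm])
        null[b] = _fstat(expr.values, qb, df_spline)
    pooled = np.sort(null.ravel())
    pooled = pooled[np.isfinite(pooled)]
    m_null = len(pooled)
    # upper-tail permutation p with +1 smoothing (never exactly 0)
    exceed = m_null - np.searchsorted(pooled, f_obs, side="left")
    p_raw = (1.0 + exceed) / (1.0 + m_null)

    g = expr.n_genes
    p_bonf = np.minimum(1.0, p_raw * g)
    q_bh = multipletests(p_raw, method="fdr_bh")[1]
    gate = {"bonferroni": p_bonf, "bh": q_bh, "raw": p_raw}[correction]
    return pd.DataFrame(
        {
            "gene_id": list(expr.gene_ids),
            "stat": f_obs,
            "p": p_raw,
            "p_bonferroni": p_bonf,
            "q_bh": q_bh,
            "significant": gate < alpha,
        }
    )
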