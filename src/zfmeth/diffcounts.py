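"""Two-group count statistics shared by the ChIP, small-RNA and RNA stages.

Median-of-ratios normalization, a deterministic conditional exact test
(Fisher) on pooled group counts against the library remainder, pseudocount
fold changes, and Benjamini-Hochberg FDR control.

The exact test replaces the negative-binomial tests of the packaged
differential tools: it is fully specified, enumeration-verifiable and
conservative at the problem sizes this package targets.  ``test_hook``
on :func:`differential_table` allows plugging an alternative per-feature
test later.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .core import CountMatrix

__all__ = [
    "DifferentialResult",
    "size_factors",
    "fisher_exact_two_sided",
    "two_group_test",
    "differential_table",
    "bh_fdr",
]


@dataclass(frozen=True)
class DifferentialResult:
    feature: object
    log2_fold_change: float  # group A over group B, pseudocount applied
    p_value: float
    q_value: float | None = None


def size_factors(
    counts: pd.DataFrame | CountMatrix, fallback_to_totals: bool = False
) -> pd.Series:
    """Median-of-ratios per-sample scale factors, rescaled to geometric mean 1.

    factor_s = median over features (positive in every sample) of
    count_fs / geometric-mean_f.  When no feature is positive in all
    samples, raises unless ``fallback_to_totals`` is set, in which case
    total-count scaling is used.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    if counts.shape[1] == 1:
        return pd.Series(1.0, index=counts.columns)
    arr = counts.to_numpy(dtype=float)
    all_pos = (arr > 0).all(axis=1)
    if not all_pos.any():
        if not fallback_to_totals:
            raise ValueError(
                "no feature has positive counts in every sample; pass "
                "fallback_to_totals=True to scale by library totals"
            )
        factors = arr.sum(axis=0)
        if (factors <= 0).any():
            raise ValueError("a sample has zero total counts")
    else:
        pos = arr[all_pos]
        log_gm = np.log(pos).mean(axis=1, keepdims=True)
        factors = np.exp(np.median(np.log(pos) - log_gm, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns)


def fisher_exact_two_sided(
    a, b, c, d, *, rel_tol: float = 1e-7, max_cells: int = 4_000_000
) -> np.ndarray:
    """Vectorised two-sided Fisher exact p-values for tables [[a, b], [c, d]].

    The two-sided p is the hypergeometric probability mass of every table
    with the observed margins whose point probability does not exceed the
    observed one (within ``rel_tol``, as in R's fisher.test).  Agrees with
    ``scipy.stats.fisher_exact`` but runs in chunks over many tables.
    """
    a, b, c, d = np.broadcast_arrays(
        *(np.asarray(x, dtype=np.int64) for x in (a, b, c, d))
    )
    shape = a.shape
    a, b, c, d = (x.ravel() for x in (a, b, c, d))
    if ((a < 0) | (b < 0) | (c < 0) | (d < 0)).any():
        raise ValueError("table entries must be non-negative")
    M = a + b + c + d  # grand total
    K = a + b  # first-row margin
    N = a + c  # first-column margin
    lo = np.maximum(0, K + N - M)
    hi = np.minimum(K, N)
    width = hi - lo + 1

    # log pmf at the lower support end, one gammaln evaluation per table;
    # the rest of the support follows by the hypergeometric ratio recurrence
    # pmf(k+1)/pmf(k) = (K-k)(N-k) / ((k+1)(M-K-N+k+1)).
    with np.errstate(invalid="ignore"):
        lpmf_lo = (
            gammaln(K + 1) - gammaln(lo + 1) - gammaln(K - lo + 1)
            + gammaln(M - K + 1) - gammaln(N - lo + 1)
            - gammaln(M - K - N + lo + 1)
            + gammaln(N + 1) + gammaln(M - N + 1) - gammaln(M + 1)
        )

    p = np.ones(a.size, dtype=float)
    live = np.nonzero(M > 0)[0]
    # sort by support width so padded chunks waste little work
    live = live[np.argsort(width[live], kind="stable")]
    log_tol = np.log1p(rel_tol)
    start = 0
    while start < live.size:
        w = int(width[live[start]])
        rows = max(1, min(live.size - start, max_cells // max(w, 1)))
        idx = live[start : start + rows]
        start += rows
        mw = int(width[idx].max())
        k = lo[idx, None] + np.arange(mw)[None, :]
        valid = k <= hi[idx, None]
        ratio_valid = k < hi[idx, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            logr = (
                np.log(K[idx, None] - k)
                + np.log(N[idx, None] - k)
                - np.log(k + 1)
                - np.log(M[idx, None] - K[idx, None] - N[idx, None] + k + 1)
            )
        logr = np.where(ratio_valid, logr, 0.0)
        lpmf = np.empty_like(logr)
        lpmf[:, 0] = lpmf_lo[idx]
        if mw > 1:
            lpmf[:, 1:] = lpmf_lo[idx, None] + np.cumsum(logr[:, :-1], axis=1)
        lpmf_obs = lpmf[np.arange(idx.size), (a[idx] - lo[idx])]
        take = valid & (lpmf <= lpmf_obs[:, None] + log_tol)
        p[idx] = np.minimum(
            np.exp(lpmf, where=take, out=np.zeros_like(lpmf)).sum(axis=1), 1.0
        )
    return p.reshape(shape)


def bh_fdr(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (clipped to 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.empty(0, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _safe_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios, falling back to totals, then to unit factors
    (degenerate all-zero matrices)."""
    try:
        return size_factors(counts)
    except ValueError:
        try:
            return size_factors(counts, fallback_to_totals=True)
        except ValueError:
            return pd.Series(1.0, index=counts.columns)


def _group_columns(matrix: CountMatrix, group_a: str | None, group_b: str | None):
    names = matrix.group_names
    if group_a is None or group_b is None:
        if len(names) != 2:
            raise ValueError(
                f"matrix has groups {names}; exactly two are required unless "
                "group_a/group_b are given"
            )
        if group_a is None and group_b is None:
            group_a, group_b = names
        elif group_a is None:
            group_a = next(n for n in names if n != group_b)
        else:
            group_b = next(n for n in names if n != group_a)
    return (
        group_a,
        group_b,
        matrix.group_samples(group_a),
        matrix.group_samples(group_b),
    )


def differential_table(
    matrix: CountMatrix,
    group_a: str | None = None,
    group_b: str | None = None,
    pseudocount: float = 1.0,
    factors: pd.Series | None = None,
    test_hook: Callable[[np.ndarray, np.ndarray, np.ndarray, np.ndarray], np.ndarray]
    | None = None,
) -> pd.DataFrame:
    """Per-feature two-group differential test over the whole matrix.

    For each feature the 2x2 table is (summed raw counts in group A, in
    group B) x (summed counts of all other features in A, in B) — the
    feature against its library remainder — tested with the two-sided
    conditional exact test.  log2 fold changes come from normalized group
    means with ``pseudocount`` added; q-values are BH across features.

    Returns a DataFrame indexed like the matrix with columns
    ``log2fc, p, q, mean_a, mean_b``.
    """
    group_a, group_b, cols_a, cols_b = _group_columns(matrix, group_a, group_b)
    counts = matrix.counts
    if factors is None:
        factors = _safe_factors(counts[cols_a + cols_b])
    norm = counts[cols_a + cols_b] / factors
    mean_a = norm[cols_a].mean(axis=1).to_numpy()
    mean_b = norm[cols_b].mean(axis=1).to_numpy()
    log2fc = np.log2(mean_a + pseudocount) - np.log2(mean_b + pseudocount)

    sum_a = counts[cols_a].sum(axis=1).to_numpy()
    sum_b = counts[cols_b].sum(axis=1).to_numpy()
    rest_a = sum_a.sum() - sum_a
    rest_b = sum_b.sum() - sum_b
    test = test_hook or fisher_exact_two_sided
    p = np.asarray(test(sum_a, sum_b, rest_a, rest_b), dtype=float)
    zero = (sum_a + sum_b) == 0
    p[zero] = 1.0
    log2fc[zero] = 0.0
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "q": bh_fdr(p),
            "mean_a": mean_a,
            "mean_b": mean_b,
        },
        index=counts.index,
    )


def two_group_test(
    matrix: CountMatrix,
    feature,
    pseudocount: float = 1.0,
    group_a: str | None = None,
    group_b: str | None = None,
) -> DifferentialResult:
    """Single-feature view of :func:`differential_table` (no q-value)."""
    group_a, group_b, cols_a, cols_b = _group_columns(matrix, group_a, group_b)
    counts = matrix.counts
    if feature not in counts.index:
        raise KeyError(f"unknown feature: {feature!r}")
    factors = _safe_factors(counts[cols_a + cols_b])
    norm = counts.loc[feature, cols_a + cols_b] / factors
    mean_a = float(norm[cols_a].mean())
    mean_b = float(norm[cols_b].mean())
    sum_a = int(counts.loc[feature, cols_a].sum())
    sum_b = int(counts.loc[feature, cols_b].sum())
    rest_a = int(counts[cols_a].sum().sum()) - sum_a
    rest_b = int(counts[cols_b].sum().sum()) - sum_b
    if sum_a + sum_b == 0:
        return DifferentialResult(feature, 0.0, 1.0)
    p = float(fisher_exact_two_sided(sum_a, sum_b, rest_a, rest_b))
    log2fc = float(
        np.log2(mean_a + pseudocount) - np.log2(mean_b + pseudocount)
    )
    return DifferentialResult(feature, log2fc, p)
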