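"""Weighted isotonic regression of posterior draws across doses.

Monotone dose-toxicity (and optionally dose-efficacy) relationships are
imposed *a posteriori*: each Monte-Carlo draw vector across doses is
replaced by its weighted least-squares non-decreasing fit, computed with
the pool-adjacent-violators algorithm (PAVA).  The weights are shared
across draws and equal the reciprocal of the per-dose posterior variances,
estimated empirically from the unconstrained draw matrix.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["pava", "isotonize_draws", "posterior_variance_weights"]


@njit(cache=True)
def _pava_inplace(y: np.ndarray, w: np.ndarray, out: np.ndarray) -> None:
    # stack-based PAVA: pool adjacent blocks while the weighted means violate
    n = y.shape[0]
    mean = np.empty(n)
    weight = np.empty(n)
    size = np.empty(n, dtype=np.int64)
    top = -1
    for i in range(n):
        top += 1
        mean[top] = y[i]
        weight[top] = w[i]
        size[top] = 1
        while top > 0 and mean[top - 1] > mean[top]:
            tot = weight[top - 1] + weight[top]
            mean[top - 1] = (weight[top - 1] * mean[top - 1] + weight[top] * mean[top]) / tot
            weight[top - 1] = tot
            size[top - 1] += size[top]
            top -= 1
    pos = 0
    for b in range(top + 1):
        for _ in range(size[b]):
            out[pos] = mean[b]
            pos += 1


@njit(cache=True)
def _pava_rows(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    out = np.empty_like(values)
    for t in range(values.shape[0]):
        _pava_inplace(values[t], weights, out[t])
    return out


def pava(values, weights=None) -> np.ndarray:
    """Weighted least-squares non-decreasing fit of a vector.

    Parameters
    ----------
    values
        Finite values to monotonize, ordered by dose.
    weights
        Strictly positive weights, one per entry (equal weights if omitted).

    Returns
    -------
    The non-decreasing vector minimizing the weighted squared error; the
    weighted mean is preserved within each pooled block.
    """
    y = np.ascontiguousarray(values, dtype=np.float64)
    if y.ndim != 1:
        raise ValueError("pava expects a 1-D vector")
    if weights is None:
        w = np.ones_like(y)
    else:
        w = np.ascontiguousarray(weights, dtype=np.float64)
    if w.shape != y.shape:
        raise ValueError("values and weights must have the same length")
    if not np.all(np.isfinite(y)):
        raise ValueError("values must be finite")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be strictly positive and finite")
    out = np.empty_like(y)
    _pava_inplace(y, w, out)
    return out


def posterior_variance_weights(draws: np.ndarray) -> np.ndarray:
    """Reciprocal-variance weights from a T x J draw matrix.

    A dose whose draws are (numerically) constant gets the largest finite
    weight among the others, keeping the weight vector positive and finite.
    """
    draws = np.asarray(draws, dtype=np.float64)
    var = draws.var(axis=0)
    w = np.empty_like(var)
    pos = var > 0
    w[pos] = 1.0 / var[pos]
    if not pos.all():
        w[~pos] = w[pos].max() if pos.any() else 1.0
    return w


def isotonize_draws(draws: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Apply weighted PAVA to every row (draw) of a T x J matrix.

    ``weights`` default to the reciprocal of the per-dose empirical
    variances of the unconstrained draws, fixed across all rows.
    """
    draws = np.ascontiguousarray(draws, dtype=np.float64)
    if draws.ndim != 2:
        raise ValueError("draws must be a T x J matrix")
    if weights is None:
        weights = posterior_variance_weights(draws)
    else:
        weights = np.ascontiguousarray(weights, dtype=np.float64)
        if weights.shape != (draws.shape[1],):
            raise ValueError("weights must have one entry per dose")
        if np.any(weights <= 0) or not np.all(np.isfinite(weights)):
            raise ValueError("weights must be strictly positive and finite")
    return _pava_rows(draws, weights)
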