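"""Natural cubic spline bases.

The truncated-power natural cubic spline basis (linear beyond the boundary
knots) used for the exposure axis, the lag axis and the long-term time trend.
With K knots (boundaries included) the basis spans K-1 functions excluding the
intercept, so ``df`` non-intercept functions require ``df + 1`` knots.
"""

from __future__ import annotations

import numpy as np


def natural_cubic_basis(
    x: np.ndarray, knots: np.ndarray, intercept: bool = False
) -> np.ndarray:
    """Evaluate a natural cubic spline basis at ``x``.

    Parameters
    ----------
    x : array_like
        Evaluation points; NaN rows propagate to NaN.
    knots : array_like
        All knots, boundaries included, strictly increasing, length >= 2.
    intercept : bool
        Prepend a constant column.

    Returns
    -------
    ndarray of shape ``(len(x), len(knots) - 1 + intercept)``.
    """
    k = np.asarray(knots, dtype=float)
    if k.ndim != 1 or k.size < 2:
        raise ValueError("need at least two knots")
    if np.any(np.diff(k) <= 0):
        raise ValueError("knots must be strictly increasing")
    x = np.asarray(x, dtype=float)
    shape = x.shape
    x = x.ravel()
    K = k.size

    def trunc3(v):
        return np.clip(v, 0.0, None) ** 3

    cols = [x]
    if K >= 3:
        # d_j(x) = [(x-k_j)_+^3 - (x-k_K)_+^3] / (k_K - k_j)
        last = trunc3(x - k[-1])
        d = [(trunc3(x - k[j]) - last) / (k[-1] - k[j]) for j in range(K - 1)]
        for j in range(K - 2):
            cols.append(d[j] - d[K - 2])
    B = np.column_stack(cols)
    if intercept:
        B = np.column_stack([np.ones_like(x), B])
    return B.reshape(shape + (B.shape[1],))


def knots_from_quantiles(
    x: np.ndarray, df: int, interior_probs: np.ndarray | None = None
) -> np.ndarray:
    """Knot vector (boundaries at data min/max) giving ``df`` basis functions.

    ``interior_probs`` are percentile positions in (0, 100) for the df-1
    interior knots; default equally spaced.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no finite data for knot placement")
    if df < 1:
        raise ValueError("df must be >= 1")
    n_interior = df - 1
    if interior_probs is None:
        interior_probs = np.linspace(0, 100, n_interior + 2)[1:-1]
    interior_probs = np.asarray(interior_probs, dtype=float)
    if interior_probs.size != n_interior:
        raise ValueError(f"need {n_interior} interior percentiles, got {interior_probs.size}")
    lo, hi = x.min(), x.max()
    if hi - lo <= 0:
        # constant data: open a token interval so the basis stays well defined
        pad = max(abs(lo) * 1e-6, 1e-6)
        lo, hi = lo - pad, hi + pad
        return np.linspace(lo, hi, df + 1)
    interior = np.percentile(x, interior_probs) if n_interior else np.array([])
    knots = np.concatenate([[lo], interior, [hi]])
    if np.any(np.diff(knots) <= 0):
        # degenerate quantiles (ties); fall back to equally spaced knots
        knots = np.linspace(lo, hi, df + 1)
    return knots


def log_lag_knots(lag_max: int, n_interior: int) -> np.ndarray:
    """Knots over [0, lag_max] with interior knots equally spaced in log-lag."""
    if n_interior > 0:
        interior = np.exp(np.linspace(np.log(1.0), np.log(lag_max), n_interior + 2))[1:-1]
    else:
        interior = np.array([])
    return np.concatenate([[0.0], interior, [float(lag_max)]])
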