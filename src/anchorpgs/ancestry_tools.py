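"""Ancestry summary utilities: mixture fitting, entropy, kernel smoothing."""

from __future__ import annotations

import numpy as np
from scipy.optimize import nnls

__all__ = ["nnls_mixture", "ancestry_entropy", "kernel_smooth", "adaptive_bandwidth"]


def nnls_mixture(target, reference_matrix) -> np.ndarray:
    """Express a target vector as a normalized non-negative mix of reference rows.

    Solves ``min || R^T c - target ||`` subject to ``c >= 0`` and rescales
    the solution to sum to one.
    """
    target = np.asarray(target, dtype=float).ravel()
    R = np.atleast_2d(np.asarray(reference_matrix, dtype=float))
    if R.shape[1] != target.shape[0]:
        raise ValueError("reference rows must have the same length as the target")
    if np.all(R == 0):
        raise ValueError("reference matrix is all zero")
    coef, _ = nnls(R.T, target)
    total = coef.sum()
    if total <= 0:
        raise ValueError("all-zero NNLS solution; target orthogonal to reference cone")
    return coef / total


def ancestry_entropy(coefficients, subset=None) -> float:
    """Shannon entropy (nats) of mixture coefficients, renormalized over a subset.

    Zero components contribute nothing (0 * log 0 = 0).
    """
    a = np.asarray(coefficients, dtype=float).ravel()
    if subset is not None:
        a = a[np.asarray(subset)]
    if np.any(a < 0):
        raise ValueError("coefficients must be non-negative")
    total = a.sum()
    if total <= 0:
        raise ValueError("subset coefficients are all zero")
    p = a / total
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum())


def adaptive_bandwidth(points, k: int = 10) -> np.ndarray:
    """Per-point precision q_p = 1 / (2 d_k^2), d_k = k-nearest-sample distance."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = pts.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of points")
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=-1)
    dk2 = np.sort(d2, axis=1)[:, k]  # column 0 is self-distance
    return 1.0 / (2.0 * np.maximum(dk2, 1e-300))


def kernel_smooth(points, values, grid, q=1.0) -> np.ndarray:
    """Gaussian-kernel weighted mean of point values at each grid location.

    Weights are ``exp(-q * squared distance)`` normalized to sum to one at
    every grid location, so the field is bounded by the value range.  ``q``
    may be a scalar or a per-grid-point array (adaptive bandwidth).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    vals = np.asarray(values, dtype=float).ravel()
    gr = np.atleast_2d(np.asarray(grid, dtype=float))
    if pts.shape[0] == 0:
        raise ValueError("need at least one input point")
    if vals.shape[0] != pts.shape[0]:
        raise ValueError("values must match points")
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("bandwidth parameter q must be positive")
    d2 = ((gr[:, None, :] - pts[None, :, :]) ** 2).sum(axis=-1)
    logw = -(q if q.ndim == 0 else q[:, None]) * d2
    logw -= logw.max(axis=1, keepdims=True)  # stabilize before exponentiating
    w = np.exp(logw)
    w /= w.sum(axis=1, keepdims=True)
    return w @ vals
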