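"""Morphological disparity: Procrustes variance and its permutation test."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DisparityResult:
    variance_a: float
    variance_b: float
    abs_difference: float
    z: float
    p: float
    n_perm: int


def _as_matrix(shapes) -> np.ndarray:
    x = np.asarray(shapes, dtype=float)
    if x.ndim == 3:                      # (n, k, 2) configurations
        x = x.reshape(x.shape[0], -1)
    if x.ndim != 2:
        raise ValueError(f"expected (n, p) shapes; got {x.shape}")
    return x


def procrustes_variance(shapes) -> float:
    """Mean squared Procrustes distance of aligned shapes to their mean.

    Equals the trace of the sample covariance matrix with divisor n.
    """
    x = _as_matrix(shapes)
    if x.shape[0] < 2:
        raise ValueError("need at least two shapes")
    dev = x - x.mean(axis=0)
    return float((dev ** 2).sum() / x.shape[0])


def disparity_test(group_a, group_b, n_perm: int = 10000,
                   seed: int | None = None) -> DisparityResult:
    """Permutation test for a difference in Procrustes variance.

    Group labels are permuted ``n_perm`` times; the p-value uses the
    (1 + exceedances)/(n_perm + 1) convention.
    """
    a, b = _as_matrix(group_a), _as_matrix(group_b)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least two shapes")
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share a common alignment / dimension")
    var_a, var_b = procrustes_variance(a), procrustes_variance(b)
    observed = abs(var_a - var_b)

    pooled = np.vstack([a, b])
    n_a, n = a.shape[0], a.shape[0] + b.shape[0]
    rng = np.random.default_rng(seed)
    # vectorised label permutations: Procrustes variance of a group is
    # mean |x|^2 minus |group mean|^2
    sq = (pooled ** 2).sum(axis=1)
    null = np.empty(n_perm)
    chunk = max(1, int(2e7 // (n * pooled.shape[1])))
    for start in range(0, n_perm, chunk):
        size = min(chunk, n_perm - start)
        idx = np.argsort(rng.random((size, n)), axis=1)
        ia, ib = idx[:, :n_a], idx[:, n_a:]
        perm_var_a = sq[ia].mean(axis=1) - (pooled[ia].mean(axis=1) ** 2).sum(axis=1)
        perm_var_b = sq[ib].mean(axis=1) - (pooled[ib].mean(axis=1) ** 2).sum(axis=1)
        null[start:start + size] = np.abs(perm_var_a - perm_var_b)
    sd = float(null.std(ddof=0))
    z = (observed - float(null.mean())) / sd if sd > 0 else 0.0
    p = (1.0 + float((null >= observed).sum())) / (n_perm + 1.0)
    return DisparityResult(var_a, var_b, observed, z, p, n_perm)
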