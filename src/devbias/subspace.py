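"""Common-subspace comparison of covariance matrices.

Two covariance matrices are compared along the eigenvectors of a third,
independently estimated reference matrix (by convention the phenotypic
matrix P of *S. fulgens*): the variance of matrix X along reference
eigenvector ``k_i`` is ``k_i' X k_i``, and the natural-log variances of the
compared matrix are regressed (OLS) on those of the developmental matrix D
over the first ``k`` dimensions, ``k`` being the rank of the lower-rank
matrix.  Resampled matrix draws (REML-MVN) give percentile confidence
limits for the coefficient of determination and slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .covmatrix import CovMatrix


@dataclass
class ProjectionBasis:
    reference_id: str
    eigenvectors: np.ndarray   # (p, p), columns ordered by descending eigenvalue
    eigenvalues: np.ndarray    # nonincreasing

    @property
    def p(self) -> int:
        return self.eigenvectors.shape[0]


@dataclass
class SubspaceResult:
    k: int
    log_var_x: np.ndarray
    log_var_d: np.ndarray
    r2: float
    slope_b: float
    intercept: float
    dropped_dims: tuple[int, ...] = ()
    ci_r2: tuple[float, float] | None = None
    ci_slope: tuple[float, float] | None = None
    n_resamples: int = 0
    dropped_draw_count: int = 0


def eigenbasis(reference: CovMatrix | np.ndarray) -> ProjectionBasis:
    """Full orthonormal eigenbasis of a symmetric reference matrix,
    eigenvalues descending; each eigenvector's largest-magnitude entry is
    made positive (signs do not affect quadratic forms)."""
    if isinstance(reference, CovMatrix):
        mat, ref_id = reference.matrix, f"{reference.label}:{reference.taxon}"
    else:
        mat = np.asarray(reference, dtype=float)
        ref_id = "reference"
    if np.abs(mat - mat.T).max() > 1e-8 * max(np.abs(mat).max(), 1e-300):
        raise ValueError("reference matrix is not symmetric")
    w, v = np.linalg.eigh((mat + mat.T) / 2.0)
    w, v = w[::-1], v[:, ::-1]
    flip = np.sign(v[np.argmax(np.abs(v), axis=0), np.arange(v.shape[1])])
    flip[flip == 0] = 1.0
    return ProjectionBasis(ref_id, v * flip, w)


def project_variances(x: CovMatrix | np.ndarray, basis: ProjectionBasis,
                      k: int | None = None) -> np.ndarray:
    """Variances of X along the first k reference eigenvectors:
    ``v_i = k_i' X k_i``."""
    mat = x.matrix if isinstance(x, CovMatrix) else np.asarray(x, dtype=float)
    if mat.shape[0] != basis.p:
        raise ValueError("dimension mismatch between matrix and basis")
    k = basis.p if k is None else int(k)
    if not 1 <= k <= basis.p:
        raise ValueError(f"k must be in [1, {basis.p}]")
    vecs = basis.eigenvectors[:, :k]
    return np.einsum("ij,jl,li->i", vecs.T, mat, vecs)


def _loglog_fit(vx: np.ndarray, vd: np.ndarray) -> tuple[float, float, float, tuple[int, ...]]:
    usable = (vx > 0) & (vd > 0)
    dropped = tuple(np.nonzero(~usable)[0].tolist())
    if usable.sum() < 3:
        raise ValueError("fewer than 3 usable dimensions with positive variance")
    lx, ld = np.log(vx[usable]), np.log(vd[usable])
    ld_c = ld - ld.mean()
    slope = float((ld_c @ (lx - lx.mean())) / (ld_c @ ld_c))
    intercept = float(lx.mean() - slope * ld.mean())
    denom = np.var(lx) * np.var(ld)
    r2 = float(np.cov(lx, ld, bias=True)[0, 1] ** 2 / denom) if denom > 0 else 1.0
    return r2, slope, intercept, dropped


def compare_matrices(x: CovMatrix | np.ndarray, d: CovMatrix | np.ndarray,
                     basis: ProjectionBasis, k: int) -> SubspaceResult:
    """Log-log regression of X's variances on D's variances along the
    first ``k`` reference eigenvectors (D is the predictor).

    Dimensions where either projected variance is nonpositive are dropped
    and recorded; fewer than three usable dimensions is an error.
    """
    vx = project_variances(x, basis, k)
    vd = project_variances(d, basis, k)
    r2, slope, intercept, dropped = _loglog_fit(vx, vd)
    keep = np.array([i for i in range(k) if i not in dropped])
    return SubspaceResult(
        k=k, log_var_x=np.log(vx[keep]), log_var_d=np.log(vd[keep]),
        r2=r2, slope_b=slope, intercept=intercept, dropped_dims=dropped,
    )


def subspace_ci(x_draws, d_draws, basis: ProjectionBasis, k: int,
                seed: int | None = None,
                point: SubspaceResult | None = None) -> SubspaceResult:
    """Percentile 95% confidence limits for r-squared and slope from
    resampled matrix draws.

    Equal-length draw lists are paired by index; unequal lists are
    cross-paired at random (seeded).  Draws with fewer than three usable
    dimensions are dropped and counted.
    """
    x_draws, d_draws = list(x_draws), list(d_draws)
    if min(len(x_draws), len(d_draws)) < 10:
        raise ValueError("need at least 10 draws per matrix")
    import warnings
    if min(len(x_draws), len(d_draws)) < 100:
        warnings.warn("fewer than 100 draws: confidence limits will be crude",
                      stacklevel=2)
    if len(x_draws) == len(d_draws):
        pairs = list(zip(x_draws, d_draws))
    else:
        rng = np.random.default_rng(seed)
        n = max(len(x_draws), len(d_draws))
        pairs = [
            (x_draws[i], d_draws[j])
            for i, j in zip(rng.integers(0, len(x_draws), n),
                            rng.integers(0, len(d_draws), n))
        ]
    r2s, slopes, dropped = [], [], 0
    vecs = basis.eigenvectors[:, :k]
    for xm, dm in pairs:
        mx = xm.matrix if isinstance(xm, CovMatrix) else xm
        md = dm.matrix if isinstance(dm, CovMatrix) else dm
        vx = np.einsum("ij,jl,li->i", vecs.T, mx, vecs)
        vd = np.einsum("ij,jl,li->i", vecs.T, md, vecs)
        try:
            r2, slope, _, _ = _loglog_fit(vx, vd)
        except ValueError:
            dropped += 1
            continue
        r2s.append(r2)
        slopes.append(slope)
    if len(r2s) < 10:
        raise ValueError("fewer than 10 usable draws")
    ci_r2 = tuple(np.percentile(r2s, [2.5, 97.5]))
    ci_slope = tuple(np.percentile(slopes, [2.5, 97.5]))
    if point is None:
        point = SubspaceResult(k=k, log_var_x=np.array([]), log_var_d=np.array([]),
                               r2=float(np.median(r2s)), slope_b=float(np.median(slopes)),
                               intercept=float("nan"))
    return SubspaceResult(
        k=point.k, log_var_x=point.log_var_x, log_var_d=point.log_var_d,
        r2=point.r2, slope_b=point.slope_b, intercept=point.intercept,
        dropped_dims=point.dropped_dims, ci_r2=ci_r2, ci_slope=ci_slope,
        n_resamples=len(r2s), dropped_draw_count=dropped,
    )
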