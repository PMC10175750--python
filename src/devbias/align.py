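"""Generalized Procrustes analysis and allometry control.

Superimposition removes translation (centering), scale (unit centroid
size) and rotation (least-squares fit to a consensus); aligned
configurations are then projected orthogonally onto the tangent space at
the consensus, leaving ``2k`` coordinates of which four directions
(translation x/y, scale, rotation) carry essentially no variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ShapeDataset


class SingularConfigurationError(ValueError):
    """All landmarks coincide; the configuration has no shape."""


@dataclass
class AlignedDataset:
    """Procrustes/tangent-space shape coordinates with centroid sizes."""

    shape_coords: np.ndarray          # (n_obs, 2k) tangent coordinates
    centroid_size: np.ndarray         # (n_obs,)
    consensus: np.ndarray             # (k, 2) mean shape
    factors: pd.DataFrame
    allometry_coef: np.ndarray | None = None   # set by residualize_allometry
    is_residualized: bool = False

    @property
    def log_centroid_size(self) -> np.ndarray:
        return np.log(self.centroid_size)

    @property
    def n_landmarks(self) -> int:
        return self.consensus.shape[0]

    def __len__(self) -> int:
        return self.shape_coords.shape[0]


def _center_and_scale(config: np.ndarray) -> tuple[np.ndarray, float]:
    centered = config - config.mean(axis=0)
    cs = float(np.sqrt((centered ** 2).sum()))
    if cs < 1e-12:
        raise SingularConfigurationError("degenerate configuration: centroid size ~ 0")
    return centered / cs, cs


def _optimal_rotation(config: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper 2-D rotation R minimizing ||config @ R - target||_F.

    In two dimensions the optimum is closed form: with H = config' target,
    cos/sin of the rotation angle are proportional to (h00 + h11,
    h01 - h10).
    """
    h = config.T @ target
    a, b = h[0, 0] + h[1, 1], h[0, 1] - h[1, 0]
    norm = np.hypot(a, b)
    if norm < 1e-300:
        return np.eye(2)
    c, s = a / norm, b / norm
    return np.array([[c, s], [-s, c]])


def _rotate_all(configs: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Vectorised optimal rotation of every (k, 2) configuration in an
    (n, k, 2) stack onto the common target."""
    h00 = np.einsum("nk,k->n", configs[:, :, 0], target[:, 0])
    h11 = np.einsum("nk,k->n", configs[:, :, 1], target[:, 1])
    h01 = np.einsum("nk,k->n", configs[:, :, 0], target[:, 1])
    h10 = np.einsum("nk,k->n", configs[:, :, 1], target[:, 0])
    a, b = h00 + h11, h01 - h10
    norm = np.hypot(a, b)
    norm[norm < 1e-300] = 1.0
    c, s = a / norm, b / norm
    out = np.empty_like(configs)
    out[:, :, 0] = c[:, None] * configs[:, :, 0] - s[:, None] * configs[:, :, 1]
    out[:, :, 1] = s[:, None] * configs[:, :, 0] + c[:, None] * configs[:, :, 1]
    return out


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance between two configurations.

    Both are centered and scaled to unit centroid size, then ``b`` is
    rotated onto ``a``; the distance is the root summed squared difference.
    """
    a_s, _ = _center_and_scale(np.asarray(a, float))
    b_s, _ = _center_and_scale(np.asarray(b, float))
    rot = _optimal_rotation(b_s, a_s)
    return float(np.sqrt(((b_s @ rot - a_s) ** 2).sum()))


def _canonical_orientation(consensus: np.ndarray) -> np.ndarray:
    """Rotation taking a consensus to a canonical frame: major principal
    axis of the landmarks along x, the landmark furthest from the centroid
    pointing in +x.  Makes reference-free alignment invariant to the
    orientation of the raw inputs."""
    cov = consensus.T @ consensus
    _, vecs = np.linalg.eigh(cov)
    major = vecs[:, -1]
    far = consensus[np.argmax((consensus ** 2).sum(axis=1))]
    if far @ major < 0:
        major = -major
    c, s = major[0], major[1]
    # rotation sending `major` to (1, 0)
    return np.array([[c, s], [-s, c]])


def _nuisance_basis(consensus_flat: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the scale and rotation directions at the
    consensus (translation is removed exactly by centering)."""
    c = consensus_flat / np.linalg.norm(consensus_flat)
    xy = c.reshape(-1, 2)
    rot = np.column_stack([-xy[:, 1], xy[:, 0]]).ravel()   # infinitesimal rotation
    rot = rot - (rot @ c) * c
    rot /= np.linalg.norm(rot)
    return np.stack([c, rot])


def gpa_align(data: ShapeDataset, reference: np.ndarray | None = None,
              reflect_sides: bool = False, tol: float = 1e-12,
              max_iter: int = 200) -> AlignedDataset:
    """Generalized Procrustes superimposition of a landmark dataset.

    Parameters
    ----------
    data : dataset of raw configurations (arbitrary units).
    reference : optional (k, 2) consensus; when given every configuration is
        rotated to this target (one pass), otherwise the consensus is
        iteratively re-estimated.
    reflect_sides : mirror left-side configurations (negate x) before
        alignment so left and right wings occupy the same shape space; the
        matching-symmetry convention, landmark correspondence preserved.
    """
    if len(data) < 2:
        raise ValueError("need at least two configurations to align")
    coords = data.coords_array().astype(float)
    if reflect_sides:
        if "side" not in data.factors.columns:
            raise ValueError("reflect_sides requires a 'side' factor column")
        left = (data.factors["side"] == "left").to_numpy()
        coords[left, :, 0] *= -1.0

    n = coords.shape[0]
    scaled = np.empty_like(coords)
    sizes = np.empty(n)
    for i in range(n):
        scaled[i], sizes[i] = _center_and_scale(coords[i])

    if reference is not None:
        target, _ = _center_and_scale(np.asarray(reference, float))
        scaled = _rotate_all(scaled, target)
    else:
        target = scaled[0].copy()
        for _ in range(max_iter):
            scaled = _rotate_all(scaled, target)
            new_target, _ = _center_and_scale(scaled.mean(axis=0))
            # keep the consensus orientation stable across iterations
            new_target = new_target @ _optimal_rotation(new_target, target)
            change = float(((new_target - target) ** 2).sum())
            target = new_target
            if change < tol:
                break
        else:
            warnings.warn("GPA did not converge within max_iter", stacklevel=2)
        rot = _canonical_orientation(target)
        target = target @ rot.T
        scaled = _rotate_all(scaled, target)

    consensus = scaled.mean(axis=0)
    flat = scaled.reshape(n, -1)
    cons_flat = consensus.ravel()

    # orthogonal tangent projection at the consensus: remove residual
    # variation along the scale and rotation directions
    nuisance = _nuisance_basis(cons_flat)
    dev = flat - cons_flat
    dev -= (dev @ nuisance.T) @ nuisance
    tangent = cons_flat + dev

    return AlignedDataset(
        shape_coords=tangent,
        centroid_size=sizes,
        consensus=consensus,
        factors=data.factors.copy(),
    )


def residualize_allometry(aligned: AlignedDataset) -> AlignedDataset:
    """Remove allometric shape variation by multivariate regression of the
    shape coordinates on log centroid size.

    Returns a dataset whose ``shape_coords`` are the mean-centered OLS
    residuals; the 2k-vector of regression coefficients is retained in
    ``allometry_coef``.
    """
    x = aligned.log_centroid_size
    x_c = x - x.mean()
    ssx = float(x_c @ x_c)
    if ssx < 1e-12 * max(1, len(x)):
        raise ValueError("log centroid size has (near-)zero variance; "
                         "allometry cannot be estimated")
    y = aligned.shape_coords
    y_c = y - y.mean(axis=0)
    beta = (x_c @ y_c) / ssx                     # (2k,) slope vector
    residuals = y_c - np.outer(x_c, beta)
    return AlignedDataset(
        shape_coords=residuals,
        centroid_size=aligned.centroid_size.copy(),
        consensus=aligned.consensus.copy(),
        factors=aligned.factors.copy(),
        allometry_coef=beta,
        is_residualized=True,
    )
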