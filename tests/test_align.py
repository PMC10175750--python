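import numpy as np
import pytest

import devbias
from devbias.align import SingularConfigurationError, procrustes_distance
from devbias.simulate import DEFAULT_MEAN_SHAPE
from tests.conftest import make_dataset


def _rot(theta):
    return np.array([[np.cos(theta), -np.sin(theta)],
                     [np.sin(theta), np.cos(theta)]])


def test_identical_triangles_distance_zero():
    tri = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
    other = 2.0 * tri @ _rot(np.pi / 2).T
    assert procrustes_distance(tri, other) < 1e-12


def test_distance_matches_rotation_grid_search(rng):
    """Brute-force minimisation over rotation angle agrees with the
    closed-form Procrustes distance."""
    for _ in range(5):
        a = rng.normal(size=(3, 2))
        b = rng.normal(size=(3, 2))
        d = procrustes_distance(a, b)
        a_s = a - a.mean(0); a_s /= np.sqrt((a_s ** 2).sum())
        b_s = b - b.mean(0); b_s /= np.sqrt((b_s ** 2).sum())
        grid = np.arange(0.0, 2 * np.pi, 1e-4)
        best = min(np.sqrt(((b_s @ _rot(t).T - a_s) ** 2).sum()) for t in grid)
        assert abs(d - best) < 1e-6


def test_alignment_invariance_to_similarity_transforms(rng):
    """Rotating/translating/scaling raw inputs leaves every aligned shape
    coordinate unchanged (canonical consensus orientation)."""
    base = DEFAULT_MEAN_SHAPE + rng.normal(0, 0.03, (15, 11, 2))
    al1 = devbias.gpa_align(make_dataset(base))
    transformed = np.stack([
        rng.uniform(0.5, 3.0) * c @ _rot(rng.uniform(0, 2 * np.pi)).T
        + rng.normal(0, 5, 2)
        for c in base
    ])
    al2 = devbias.gpa_align(make_dataset(transformed))
    assert np.abs(al1.shape_coords - al2.shape_coords).max() < 1e-8


def test_align_to_own_consensus_is_fixed_point(rng):
    base = DEFAULT_MEAN_SHAPE + rng.normal(0, 0.02, (10, 11, 2))
    al1 = devbias.gpa_align(make_dataset(base))
    al2 = devbias.gpa_align(make_dataset(base), reference=al1.consensus)
    assert np.abs(al2.consensus - al1.consensus).max() < 1e-10
    assert np.abs(al2.shape_coords - al1.shape_coords).max() < 1e-10


def test_unit_centroid_size_and_nuisance_variance(rng):
    base = DEFAULT_MEAN_SHAPE + rng.normal(0, 0.03, (40, 11, 2))
    al = devbias.gpa_align(make_dataset(2.5 * base))
    # column means equal the flattened consensus
    np.testing.assert_allclose(al.shape_coords.mean(axis=0),
                               al.consensus.ravel(), atol=1e-12)
    # centroid sizes recorded from pre-scaling configurations
    assert np.all(al.centroid_size > 0)
    # variance along translation/scale/rotation directions is negligible
    dev = al.shape_coords - al.consensus.ravel()
    total = (dev ** 2).sum()
    c = al.consensus.ravel() / np.linalg.norm(al.consensus)
    rot = np.column_stack([-al.consensus[:, 1], al.consensus[:, 0]]).ravel()
    rot -= (rot @ c) * c
    rot /= np.linalg.norm(rot)
    tx = np.tile([1.0, 0.0], 11) / np.sqrt(11)
    ty = np.tile([0.0, 1.0], 11) / np.sqrt(11)
    for direction in (c, rot, tx, ty):
        assert ((dev @ direction) ** 2).sum() < 1e-10 * total


def test_degenerate_configuration_rejected():
    degenerate = np.ones((11, 2))
    with pytest.raises(SingularConfigurationError):
        devbias.gpa_align(make_dataset([degenerate, DEFAULT_MEAN_SHAPE]))


def test_reflect_sides_superimposes_mirrored_wings(rng):
    shape = DEFAULT_MEAN_SHAPE + rng.normal(0, 0.01, (11, 2))
    left = shape * np.array([-1.0, 1.0])
    ds = make_dataset([shape, left], sides=["right", "left"],
                      individuals=["i1", "i1"], replicates=[1, 2])
    al = devbias.gpa_align(ds, reflect_sides=True)
    d = np.abs(al.shape_coords[0] - al.shape_coords[1]).max()
    assert d < 1e-10


# ---------------------------------------------------------------- allometry


def test_allometry_exact_recovery_of_injected_slope(rng):
    n = 50
    base = DEFAULT_MEAN_SHAPE + rng.normal(0, 0.02, (n, 11, 2))
    al = devbias.gpa_align(make_dataset(base))
    log_cs = rng.normal(0, 0.2, n)
    al.centroid_size = np.exp(log_cs)
    coords = al.shape_coords.copy()
    coords[:, 3] = coords[:, 3].mean() + 0.5 * log_cs   # inject pure allometry
    al.shape_coords = coords
    res = devbias.residualize_allometry(al)
    assert abs(res.allometry_coef[3] - 0.5) < 1e-8
    # residuals orthogonal to log centroid size, coordinate-wise
    x = log_cs - log_cs.mean()
    corr = np.abs(res.shape_coords.T @ x) / (np.linalg.norm(x) + 1e-300)
    assert corr.max() < 1e-10


def test_allometry_zero_slope_returns_centered_inputs(rng):
    n = 200
    base = DEFAULT_MEAN_SHAPE + rng.normal(0, 0.02, (n, 11, 2))
    al = devbias.gpa_align(make_dataset(base))
    al.centroid_size = np.exp(rng.normal(0, 0.2, n))   # size independent of shape
    res = devbias.residualize_allometry(al)
    # coefficient norm is OLS noise around zero
    assert np.linalg.norm(res.allometry_coef) < 0.05
    centered = al.shape_coords - al.shape_coords.mean(axis=0)
    assert np.abs(res.shape_coords - centered).max() < 0.02


def test_allometry_requires_size_variation(rng):
    base = DEFAULT_MEAN_SHAPE + rng.normal(0, 0.02, (5, 11, 2))
    al = devbias.gpa_align(make_dataset(base))
    al.centroid_size = np.full(5, 2.0)
    with pytest.raises(ValueError, match="variance"):
        devbias.residualize_allometry(al)
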