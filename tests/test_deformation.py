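import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import devbias
from devbias.deformation import (e_beta, e_beta_ratio,
                                 estimate_deformation_vector,
                                 randomization_test)


def _random_psd(seed, p=22):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(p, p))
    return (a @ a.T) / p


def test_hand_quadratic_form():
    d = np.array([[2.0, 1.0], [1.0, 2.0]])
    assert e_beta(d, np.array([1.0, 1.0])) == pytest.approx(3.0)


def test_isotropic_matrix_gives_constant(rng):
    d = 0.7 * np.eye(9)
    for _ in range(5):
        assert e_beta(d, rng.normal(size=9)) == pytest.approx(0.7)


def test_leading_eigenvector_maximises(rng):
    d = _random_psd(3, p=8)
    w, v = np.linalg.eigh(d)
    assert e_beta(d, v[:, -1]) == pytest.approx(w[-1], rel=1e-10)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_rayleigh_quotient_bounds(seed):
    """lambda_min <= e_beta <= lambda_max for every direction."""
    d = _random_psd(seed, p=10)
    w = np.linalg.eigvalsh(d)
    beta = np.random.default_rng(seed + 1).normal(size=10)
    e = e_beta(d, beta)
    assert w[0] - 1e-10 <= e <= w[-1] + 1e-10


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000),
       c=st.floats(-100, 100).filter(lambda v: abs(v) > 1e-6))
def test_scale_invariance(seed, c):
    d = _random_psd(seed, p=6)
    beta = np.random.default_rng(seed).normal(size=6)
    assert e_beta(d, c * beta) == pytest.approx(e_beta(d, beta), rel=1e-9)


def test_zero_vector_rejected():
    with pytest.raises(ValueError):
        e_beta(np.eye(3), np.zeros(3))


def test_ratio_isotropic_is_one_over_p():
    p = 22
    ratio = e_beta_ratio(np.eye(p), np.random.default_rng(0).normal(size=p))
    assert ratio == pytest.approx(1.0 / p, rel=1e-10)


def test_ratio_bounded_by_leading_eigenvalue_share(rng):
    d = _random_psd(11, p=12)
    w = np.linalg.eigvalsh(d)
    for _ in range(10):
        r = e_beta_ratio(d, rng.normal(size=12))
        assert 0 <= r <= w[-1] / np.trace(d) + 1e-12


# ------------------------------------------------------------ randomization


def test_isotropic_null_gives_p_one():
    d = np.eye(22)
    beta = np.random.default_rng(1).normal(size=22)
    res = randomization_test(d, beta, n_perm=500, seed=0)
    assert res.p == 1.0
    np.testing.assert_allclose(res.null_ratios, res.ratio, rtol=1e-9)


def test_aligned_direction_detected():
    """beta on the leading axis of a strongly anisotropic D gives a small
    p-value."""
    rng = np.random.default_rng(2)
    q, _ = np.linalg.qr(rng.normal(size=(22, 22)))
    lam = np.concatenate([[10.0], np.ones(21)])
    d = (q * lam) @ q.T
    res = randomization_test(d, q[:, 0], n_perm=10_000, seed=3)
    assert res.p < 0.01


def test_constant_beta_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        randomization_test(np.eye(4), np.ones(4), n_perm=200)


def test_null_mean_matches_exchangeable_expectation():
    """For diagonal D the permutation null mean ratio equals 1/p (each
    squared coefficient visits every variance slot equally often)."""
    rng = np.random.default_rng(4)
    d = np.diag(rng.uniform(0.1, 3.0, 16))
    beta = rng.normal(size=16)
    res = randomization_test(d, beta, n_perm=20_000, seed=5)
    assert res.null_ratios.mean() == pytest.approx(1.0 / 16, rel=0.02)


def test_sphere_null_alternative(rng):
    d = _random_psd(6, p=10)
    res = randomization_test(d, rng.normal(size=10), n_perm=500, seed=1,
                             null="sphere")
    assert 0 < res.p <= 1.0


# --------------------------------------------------------- vector estimation


def test_latitude_vector_exact_on_noiseless_means(study_spec):
    """A latitudinal shape trend injected without noise is recovered to
    machine precision by the population-mean regression."""
    spec = study_spec
    p = spec.p
    lat = np.asarray(spec.population_latitudes)
    true_beta = spec.latitude_vector
    n_pop = len(lat)
    import pandas as pd
    from devbias.align import AlignedDataset
    log_cs_dev = np.random.default_rng(0).normal(0, 0.05, n_pop)
    coords = (spec.mean_shape.ravel()[None, :]
              + np.outer(lat - lat.mean(), true_beta)
              + np.outer(log_cs_dev, spec.allometry_vector))
    factors = pd.DataFrame({
        "individual": [f"p{i}" for i in range(n_pop)],
        "population": [f"pop{i}" for i in range(n_pop)],
        "latitude_deg": lat,
    })
    al = AlignedDataset(shape_coords=coords,
                        centroid_size=np.exp(log_cs_dev + spec.log_cs_mean),
                        consensus=spec.mean_shape, factors=factors)
    vec = estimate_deformation_vector(al, "latitude")
    np.testing.assert_allclose(vec.beta, true_beta, atol=1e-10)


def test_line_design_vectors_recovered(study_spec):
    """Sex and temperature deformation vectors recovered from the
    common-garden generator with high directional accuracy."""
    line = devbias.simulate.simulate_line_dataset(study_spec)
    al = devbias.gpa_align(line, reference=study_spec.mean_shape)
    for term, truth in (("sex", study_spec.sex_vector),
                        ("temperature", study_spec.temperature_vector)):
        vec = estimate_deformation_vector(al, term)
        cos = abs(vec.beta @ truth) / (np.linalg.norm(vec.beta)
                                       * np.linalg.norm(truth))
        assert cos > 0.9, term


def test_null_term_gives_uniformish_p(study_spec):
    """A term with no true effect yields a nonsignificant randomization
    test against D.

    Residual covariance is made isotropic within the shape space so the
    estimation noise on beta has exchangeable entries (the permutation
    null); with structured residuals even a zero-effect vector inherits
    the residual principal axes.
    """
    from devbias.simulate import project_to_shape_space
    p = study_spec.p
    spec = devbias.simulate.default_spec(
        seed=77,
        temperature_vector=np.zeros(p),
        P_ind_true=project_to_shape_space(np.eye(p) * 6.2e-4 / p,
                                          study_spec.mean_shape),
    )
    line = devbias.simulate.simulate_line_dataset(spec)
    al = devbias.gpa_align(line, reference=spec.mean_shape)
    vec = estimate_deformation_vector(al, "temperature")
    res = randomization_test(spec.D_true, vec.beta, n_perm=2000, seed=8)
    assert res.p > 0.01


def test_collinear_design_rejected(study_spec):
    import pandas as pd
    from devbias.align import AlignedDataset
    coords = np.zeros((3, study_spec.p))
    factors = pd.DataFrame({
        "individual": list("abc"),
        "population": ["p1", "p1", "p1"],
        "latitude_deg": [45.0, 45.0, 45.0],
    })
    al = AlignedDataset(shape_coords=coords, centroid_size=np.ones(3) * 2,
                        consensus=study_spec.mean_shape, factors=factors)
    with pytest.raises(ValueError):
        estimate_deformation_vector(al, "latitude")
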