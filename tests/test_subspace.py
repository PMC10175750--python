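import numpy as np
import pytest

import devbias
from devbias.subspace import (compare_matrices, eigenbasis, project_variances,
                              subspace_ci)


def _psd(rng, p, scale=1.0):
    a = rng.normal(size=(p, p))
    return scale * (a @ a.T) / p


def test_hand_diagonalization():
    basis = eigenbasis(np.array([[2.0, 1.0], [1.0, 2.0]]))
    np.testing.assert_allclose(basis.eigenvalues, [3.0, 1.0], atol=1e-12)
    np.testing.assert_allclose(np.abs(basis.eigenvectors[:, 0]),
                               [1 / np.sqrt(2)] * 2, atol=1e-12)
    np.testing.assert_allclose(np.abs(basis.eigenvectors[:, 1]),
                               [1 / np.sqrt(2)] * 2, atol=1e-12)


def test_projection_onto_own_basis_gives_eigenvalues(rng):
    x = _psd(rng, 6)
    basis = eigenbasis(x)
    v = project_variances(x, basis)
    np.testing.assert_allclose(v, basis.eigenvalues, atol=1e-12)


def test_hand_projection_case():
    x = np.array([[2.0, 1.0], [1.0, 2.0]])
    v = project_variances(x, eigenbasis(x), 2)
    np.testing.assert_allclose(v, [3.0, 1.0], atol=1e-12)
    assert np.all(project_variances(np.zeros((2, 2)), eigenbasis(x)) == 0)


def test_trace_conservation_under_complete_projection(rng):
    for _ in range(10):
        x = _psd(rng, 8)
        basis = eigenbasis(_psd(rng, 8))
        v = project_variances(x, basis)
        assert v.sum() == pytest.approx(np.trace(x), abs=1e-12)


def test_basis_sign_invariance(rng):
    x = _psd(rng, 5)
    basis = eigenbasis(_psd(rng, 5))
    v1 = project_variances(x, basis)
    basis.eigenvectors = basis.eigenvectors * np.array([1, -1, 1, -1, 1])
    v2 = project_variances(x, basis)
    np.testing.assert_allclose(v1, v2, atol=1e-12)


def test_self_comparison_is_identity_line(rng):
    x = _psd(rng, 6)
    basis = eigenbasis(_psd(rng, 6))
    res = compare_matrices(x, x, basis, 6)
    assert res.r2 == pytest.approx(1.0, abs=1e-10)
    assert res.slope_b == pytest.approx(1.0, abs=1e-10)
    assert res.intercept == pytest.approx(0.0, abs=1e-8)


def test_exact_log_linear_relation():
    """X = 2 D with diagonal matrices: slope 1, r2 1, intercept ln 2."""
    d = np.diag([4.0, 2.0, 1.0])
    x = np.diag([8.0, 4.0, 2.0])
    res = compare_matrices(x, d, eigenbasis(np.eye(3)), 3)
    assert res.slope_b == pytest.approx(1.0, abs=1e-12)
    assert res.r2 == pytest.approx(1.0, abs=1e-12)
    assert res.intercept == pytest.approx(np.log(2.0), abs=1e-12)


@pytest.mark.parametrize("c", [0.1, 10.0])
def test_scaling_shifts_intercept_only(rng, c):
    x, d = _psd(rng, 7), _psd(rng, 7)
    basis = eigenbasis(_psd(rng, 7))
    res = compare_matrices(x, d, basis, 7)
    res_c = compare_matrices(c * x, d, basis, 7)
    assert res_c.slope_b == pytest.approx(res.slope_b, rel=1e-10)
    assert res_c.r2 == pytest.approx(res.r2, rel=1e-10)
    assert res_c.intercept - res.intercept == pytest.approx(np.log(c), abs=1e-10)


def test_r2_symmetry_and_slope_product_identity(rng):
    """Swapping response and predictor keeps r2; OLS slopes satisfy
    b_xy * b_yx = r2."""
    x, d = _psd(rng, 6), _psd(rng, 6)
    basis = eigenbasis(_psd(rng, 6))
    fwd = compare_matrices(x, d, basis, 6)
    rev = compare_matrices(d, x, basis, 6)
    assert fwd.r2 == pytest.approx(rev.r2, rel=1e-10)
    assert fwd.slope_b * rev.slope_b == pytest.approx(fwd.r2, rel=1e-10)


def test_too_few_dimensions_rejected(rng):
    x, d = _psd(rng, 4), _psd(rng, 4)
    with pytest.raises(ValueError):
        compare_matrices(x, d, eigenbasis(np.eye(4)), 2)


def test_nonpositive_dimensions_dropped(rng):
    basis = eigenbasis(np.eye(5))
    d = np.diag([4.0, 3.0, 2.0, 1.0, 0.5])
    x = np.diag([4.0, 3.0, 2.0, 1.0, 0.0])     # one null direction
    res = compare_matrices(x, d, basis, 5)
    # tie-handling of the identity reference makes the basis order
    # arbitrary; exactly the null direction must be dropped
    assert len(res.dropped_dims) == 1
    assert res.k == 5 and len(res.log_var_x) == 4


def test_ci_zero_width_for_constant_draws(rng):
    x, d = _psd(rng, 5), _psd(rng, 5)
    basis = eigenbasis(_psd(rng, 5))
    point = compare_matrices(x, d, basis, 5)
    res = subspace_ci([x] * 50, [d] * 50, basis, 5, point=point)
    assert res.ci_r2[0] == pytest.approx(res.ci_r2[1], abs=1e-12)
    assert res.ci_r2[0] == pytest.approx(point.r2, abs=1e-12)
    assert res.ci_slope[0] == pytest.approx(point.slope_b, abs=1e-12)


def test_ci_contains_point_estimate(rng):
    x, d = _psd(rng, 6), _psd(rng, 6)
    basis = eigenbasis(_psd(rng, 6))
    point = compare_matrices(x, d, basis, 6)
    noise = 0.02
    x_draws = [x + noise * _psd(rng, 6) for _ in range(300)]
    d_draws = [d + noise * _psd(rng, 6) for _ in range(300)]
    res = subspace_ci(x_draws, d_draws, basis, 6, point=point)
    assert res.ci_r2[0] <= point.r2 <= res.ci_r2[1]
    assert res.ci_slope[0] <= point.slope_b <= res.ci_slope[1]
    assert res.n_resamples == 300


def test_ci_requires_enough_draws(rng):
    x = _psd(rng, 5)
    basis = eigenbasis(np.eye(5))
    with pytest.raises(ValueError):
        subspace_ci([x] * 5, [x] * 5, basis, 5)


def test_ci_coverage_of_true_slope():
    """REML-MVN percentile intervals cover the generating slope at
    roughly the nominal rate (small-p simulation)."""
    from devbias.models import fit_factor_analytic
    from devbias.reml import reml_mvn_resample
    from devbias.simulate import default_spec, simulate_fa_dataset

    cover = 0
    n_rep = 40
    for rep in range(n_rep):
        spec = default_spec(seed=60_000 + rep, n_individuals=100)
        basis = devbias.eigenbasis(
            devbias.CovMatrix(spec.P2_ind_true, label="P", validate=False))
        truth = compare_matrices(spec.P_ind_true, spec.D_true, basis, 5)
        data = simulate_fa_dataset(spec)
        al = devbias.gpa_align(data, reference=spec.mean_shape, reflect_sides=True)
        al = devbias.residualize_allometry(al)
        # full-capacity fits compared over leading dimensions keep the
        # point estimate unbiased, isolating the calibration of the
        # REML-MVN percentile interval itself
        fit_d = fit_factor_analytic(al, "D", rank_q=9, seed=0, n_restarts=1)
        fit_p = fit_factor_analytic(al, "P", rank_q=9, seed=0, n_restarts=1)
        point = compare_matrices(fit_p.sigma_u, fit_d.sigma_u, basis, 5)
        x_draws = [c.matrix for c in reml_mvn_resample(fit_p, 200, seed=rep)]
        d_draws = [c.matrix for c in reml_mvn_resample(fit_d, 200, seed=rep + 1)]
        res = subspace_ci(x_draws, d_draws, basis, 5, point=point)
        cover += res.ci_slope[0] <= truth.slope_b <= res.ci_slope[1]
    assert 0.85 <= cover / n_rep <= 1.0
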