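import subprocess

import numpy as np
import pandas as pd
import pytest

import devbias
from devbias.models import estimate_R, fit_factor_analytic, sample_covariance
from devbias.reml import (Component, ParamLayout, PhyloREML, Stratum,
                          StrataREML, _fit, fit_strata_model, select_rank,
                          reml_mvn_resample)
from devbias.simulate import make_low_rank_cov


def _oneway_data(rng, n_groups, reps, sig_u, sig_e):
    u = rng.normal(0, np.sqrt(sig_u), n_groups)
    y = np.repeat(u, reps) + rng.normal(0, np.sqrt(sig_e), n_groups * reps)
    g = np.repeat(np.arange(n_groups), reps)
    return y, g


def _oneway_strata(y, g, n_groups, reps):
    gm = np.array([y[g == i].mean() for i in range(n_groups)])
    ssb = reps * ((gm - y.mean()) ** 2).sum()
    ssw = ((y - gm[g]) ** 2).sum()
    return [
        Stratum(np.array([[ssb]]), n_groups - 1, {"u": float(reps), "e": 1.0}),
        Stratum(np.array([[ssw]]), n_groups * (reps - 1), {"e": 1.0}),
    ], ssb, ssw


def test_balanced_oneway_matches_closed_form(rng):
    """REML between-group variance equals (MSB - MSW)/r on balanced
    one-way data."""
    n_g, reps = 25, 4
    y, g = _oneway_data(rng, n_g, reps, 2.0, 1.0)
    strata, ssb, ssw = _oneway_strata(y, g, n_g, reps)
    msb, msw = ssb / (n_g - 1), ssw / (n_g * (reps - 1))
    fit = fit_strata_model(strata, [Component("u", "diag", 1),
                                    Component("e", "diag", 1)], seed=0)
    assert fit.converged
    assert fit.sigma_u[0, 0] == pytest.approx((msb - msw) / reps, abs=1e-6)
    assert fit.error_variances[0] == pytest.approx(msw, abs=1e-6)


def test_oneway_matches_lme4_oracle(tmp_path, rng):
    """Independent oracle: lme4's REML variance components on the same
    balanced one-way data."""
    n_g, reps = 20, 3
    y, g = _oneway_data(rng, n_g, reps, 1.5, 0.7)
    df = pd.DataFrame({"y": y, "g": g.astype(str)})
    df.to_csv(tmp_path / "oneway.csv", index=False)
    script = tmp_path / "fit.R"
    script.write_text(
        'suppressMessages(library(lme4))\n'
        f'd <- read.csv("{tmp_path / "oneway.csv"}")\n'
        'm <- lmer(y ~ 1 + (1|g), data=d, REML=TRUE)\n'
        'vc <- as.data.frame(VarCorr(m))\n'
        'cat(vc$vcov[1], vc$vcov[2], sep="\\n")\n'
    )
    out = subprocess.run(["Rscript", str(script)], capture_output=True,
                         text=True, check=True)
    r_var_u, r_var_e = (float(v) for v in out.stdout.strip().split())
    strata, *_ = _oneway_strata(y, g, n_g, reps)
    fit = fit_strata_model(strata, [Component("u", "diag", 1),
                                    Component("e", "diag", 1)], seed=0)
    assert fit.sigma_u[0, 0] == pytest.approx(r_var_u, rel=1e-4, abs=1e-6)
    assert fit.error_variances[0] == pytest.approx(r_var_e, rel=1e-4)


def test_rank_one_loading_direction_recovered(rng):
    """A q=1 factor fit recovers the generating loading direction."""
    p, n_g, reps = 6, 500, 2
    direction = rng.normal(size=p)
    direction /= np.linalg.norm(direction)
    sigma_u = 3.0 * np.outer(direction, direction) + 0.05 * np.eye(p)
    chol = np.linalg.cholesky(sigma_u)
    u = rng.standard_normal((n_g, p)) @ chol.T
    y = np.repeat(u, reps, axis=0) + rng.standard_normal((n_g * reps, p))
    g = np.repeat(np.arange(n_g), reps)
    gm = np.stack([y[g == i].mean(0) for i in range(n_g)])
    ssb = reps * (gm - y.mean(0)).T @ (gm - y.mean(0))
    resid = y - gm[g]
    strata = [Stratum(ssb, n_g - 1, {"u": float(reps), "e": 1.0}),
              Stratum(resid.T @ resid, n_g * (reps - 1), {"e": 1.0})]
    fit = fit_strata_model(strata, [Component("u", "fa", p, 1),
                                    Component("e", "diag", p)], seed=0)
    lam = fit.loadings[:, 0]
    cos = abs(lam @ direction) / np.linalg.norm(lam)
    assert cos > 0.95


def test_parameter_count_identity():
    """Rank-q factor model: p*q - q(q-1)/2 + p loading/specific parameters
    plus p error variances, reflected in the AIC."""
    p = 22
    for q in (1, 5, 9):
        comp = Component("u", "fa", p, q)
        assert comp.n_params == p * q - q * (q - 1) // 2 + p
    layout = ParamLayout([Component("u", "fa", p, 3), Component("e", "diag", p)])
    assert layout.n_params == (p * 3 - 3 + p) + p


def test_aic_definition(small_spec):
    data = devbias.simulate.simulate_fa_dataset(small_spec)
    al = devbias.gpa_align(data, reference=small_spec.mean_shape, reflect_sides=True)
    fit = fit_factor_analytic(al, "D", rank_q=2, seed=0, n_restarts=1)
    assert fit.aic == pytest.approx(-2.0 * fit.reml_loglik + 2 * fit.n_params)


def test_rank_selection_finds_true_rank(rng):
    """AIC selection recovers a strong rank-2 structure in most
    replicates (null replicates below pick small ranks)."""
    p, n_g, reps = 6, 120, 2
    hits = 0
    n_rep = 40
    for rep_i in range(n_rep):
        rng_i = np.random.default_rng(1000 + rep_i)
        q_true = np.linalg.qr(rng_i.standard_normal((p, 2)))[0]
        sigma_u = q_true @ np.diag([6.0, 3.0]) @ q_true.T
        chol_u = np.linalg.cholesky(sigma_u + 1e-10 * np.eye(p))
        u = rng_i.standard_normal((n_g, p)) @ chol_u.T
        y = np.repeat(u, reps, axis=0) + rng_i.standard_normal((n_g * reps, p))
        g = np.repeat(np.arange(n_g), reps)
        gm = np.stack([y[g == i].mean(0) for i in range(n_g)])
        ssb = reps * (gm - y.mean(0)).T @ (gm - y.mean(0))
        resid = y - gm[g]
        strata = [Stratum(ssb, n_g - 1, {"u": float(reps), "e": 1.0}),
                  Stratum(resid.T @ resid, n_g * (reps - 1), {"e": 1.0})]
        sel = select_rank(
            lambda q: fit_strata_model(strata, [Component("u", "fa", p, q),
                                                Component("e", "diag", p)],
                                       seed=0, n_restarts=1),
            max_rank=5)
        hits += sel.chosen_rank == 2
    assert hits / n_rep >= 0.9


def test_rank_selection_on_white_noise_is_small(rng):
    p, n_g, reps = 6, 80, 2
    y = rng.standard_normal((n_g * reps, p))
    g = np.repeat(np.arange(n_g), reps)
    gm = np.stack([y[g == i].mean(0) for i in range(n_g)])
    ssb = reps * (gm - y.mean(0)).T @ (gm - y.mean(0))
    resid = y - gm[g]
    strata = [Stratum(ssb, n_g - 1, {"u": float(reps), "e": 1.0}),
              Stratum(resid.T @ resid, n_g * (reps - 1), {"e": 1.0})]
    sel = select_rank(
        lambda q: fit_strata_model(strata, [Component("u", "fa", p, q),
                                            Component("e", "diag", p)],
                                   seed=0, n_restarts=1),
        max_rank=5)
    assert sel.chosen_rank <= 1


def test_scale_invariance_of_fit(small_spec):
    """Fitting on x10,000 coordinates and rescaling matches a unit-scale
    fit within optimizer tolerance."""
    data = devbias.simulate.simulate_fa_dataset(small_spec)
    al = devbias.gpa_align(data, reference=small_spec.mean_shape, reflect_sides=True)
    fit_hi = fit_factor_analytic(al, "D", rank_q=2, scale=10000.0, seed=0, n_restarts=2)
    fit_lo = fit_factor_analytic(al, "D", rank_q=2, scale=100.0, seed=0, n_restarts=2)
    denom = np.abs(fit_hi.sigma_u).max()
    assert np.abs(fit_hi.sigma_u - fit_lo.sigma_u).max() / denom < 1e-3


def test_sample_covariance_hand_case():
    cm = sample_covariance(np.array([[-1.0], [1.0]]), divisor="n-1")
    assert cm.matrix[0, 0] == pytest.approx(2.0)
    zero = sample_covariance(np.zeros((4, 3)))
    assert np.all(zero.matrix == 0)


# ------------------------------------------------------------- resampling


def _small_fit(spec):
    data = devbias.simulate.simulate_fa_dataset(spec)
    al = devbias.gpa_align(data, reference=spec.mean_shape, reflect_sides=True)
    return fit_factor_analytic(al, "D", rank_q=2, seed=0, n_restarts=2)


def test_mvn_resample_centered_on_estimate(small_spec):
    fit = _small_fit(small_spec)
    draws = reml_mvn_resample(fit, 4000, seed=3)
    mats = np.stack([d.matrix for d in draws])
    mean = mats.mean(axis=0)
    se = mats.std(axis=0) / np.sqrt(len(draws))
    diff = np.abs(mean - fit.sigma_u)
    assert np.all(diff < 4.0 * se + 1e-12 * np.abs(fit.sigma_u).max())


def test_mvn_resample_zero_cov_returns_point_estimate(small_spec):
    fit = _small_fit(small_spec)
    p = fit.p
    fit._sampling_cov_vech = np.zeros((p * (p + 1) // 2,) * 2)
    draws = reml_mvn_resample(fit, 5, seed=0)
    for d in draws:
        np.testing.assert_allclose(d.matrix, fit.sigma_u, atol=1e-12)


def test_mvn_resample_validates_input(small_spec):
    fit = _small_fit(small_spec)
    with pytest.raises(ValueError):
        reml_mvn_resample(fit, 0)


# ------------------------------------------------------------ phylogenetic


def test_star_phylogeny_reduces_to_oneway(rng):
    """On a star tree the phylogenetic REML equals the ordinary one-way
    between-species REML fit."""
    p, n_sp, m = 3, 30, 4
    sigma_u = np.array([[2.0, 0.5, 0.2], [0.5, 1.0, 0.1], [0.2, 0.1, 0.5]])
    chol = np.linalg.cholesky(sigma_u)
    sp_eff = rng.standard_normal((n_sp, p)) @ chol.T
    y = np.repeat(sp_eff, m, axis=0) + rng.standard_normal((n_sp * m, p)) * 0.6
    g = np.repeat(np.arange(n_sp), m)
    means = np.stack([y[g == i].mean(0) for i in range(n_sp)])
    ssb = m * (means - means.mean(0)).T @ (means - means.mean(0))
    resid = y - means[g]
    comps = [Component("u", "fa", p, p), Component("e", "diag", p)]
    layout = ParamLayout(comps)
    strata_prob = StrataREML([Stratum(ssb, n_sp - 1, {"u": float(m), "e": 1.0}),
                              Stratum(resid.T @ resid, n_sp * (m - 1), {"e": 1.0})],
                             layout)
    th1, _, _ = _fit(strata_prob, layout.start_from_moments(
        strata_prob.moment_estimates()), 2, 0)
    su_strata = layout.build(layout.component("u"), th1[layout.slices["u"]])

    w, q = np.linalg.eigh(np.eye(n_sp))
    layout2 = ParamLayout(comps)
    phylo = PhyloREML(q.T @ means, q.T @ np.ones(n_sp), w, 1.0 / m, layout2,
                      resid_scatter_diag=np.diag(resid.T @ resid).copy(),
                      resid_df=n_sp * (m - 1))
    th2, _, _ = _fit(phylo, layout2.start_from_moments(
        {"u": ssb / (n_sp - 1) / m, "e": np.diag(np.diag(resid.T @ resid)
                                                 / (n_sp * (m - 1)))}), 2, 0)
    su_phylo = layout2.build(layout2.component("u"), th2[layout2.slices["u"]])
    assert np.abs(su_strata - su_phylo).max() < 1e-4


def test_phylo_gradient_matches_finite_differences(rng):
    p, n_sp, m = 4, 10, 3
    s = np.eye(n_sp)
    s[0, 1] = s[1, 0] = 0.5
    w, q = np.linalg.eigh(s)
    layout = ParamLayout([Component("u", "fa", p, 2), Component("e", "diag", p)])
    prob = PhyloREML(rng.standard_normal((n_sp, p)), q.T @ np.ones(n_sp),
                     np.clip(w, 0, None), 1.0 / m, layout,
                     resid_scatter_diag=np.abs(rng.standard_normal(p)) * 3,
                     resid_df=n_sp * (m - 1))
    theta = rng.normal(0, 0.3, layout.n_params)
    _, grad = prob.neg2_and_grad(theta)
    for i in range(0, layout.n_params, 5):
        h = 1e-6 * max(1.0, abs(theta[i]))
        up, dn = theta.copy(), theta.copy()
        up[i] += h
        dn[i] -= h
        fd = (prob.neg2(up) - prob.neg2(dn)) / (2 * h)
        assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-6)


def test_estimate_R_requires_species_coverage(small_spec):
    sp_data, tree = devbias.simulate.simulate_species_dataset(small_spec)
    rel = devbias.phylo_relationship_matrix(tree, rule="none")
    al = devbias.gpa_align(sp_data, reference=small_spec.mean_shape)
    al.factors = al.factors.copy()
    al.factors.loc[al.factors["species"] == rel.taxa[0], "species"] = rel.taxa[1]
    with pytest.raises(ValueError, match="without data"):
        estimate_R(al, rel, rank_q=2)
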