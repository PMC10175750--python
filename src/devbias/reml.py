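"""Reduced-rank (factor-analytic) multivariate REML.

Model
-----
Shape observations follow a Gaussian mixed model whose random-effect
covariance is factor-analytic, ``Sigma_u = Lambda Lambda' + diag(psi)``
with ``q`` factor columns, and whose residual covariance is diagonal with a
separate error variance per shape variable.  For the balanced designs used
throughout (individuals x sides x replicates; lines within populations;
species on a phylogeny) the restricted likelihood factorises into
independent strata: each stratum ``k`` contributes a scatter matrix ``S_k``
with ``df_k`` degrees of freedom and covariance
``V_k = sum_j c_kj Gamma_j`` linear in the component matrices.  Minus twice
the restricted log-likelihood is then

    sum_k [ df_k log|V_k| + tr(V_k^{-1} S_k) ]   (+ constant).

The phylogenetic model (species effects with covariance ``S (x) Sigma_u``)
is handled by rotating species means into the eigenbasis of the
relationship matrix ``S``, which yields independent blocks with
``V_i = delta_i Sigma_u + Sigma_e / m`` plus a GLS profiling term for the
grand mean (the REML correction).

Optimisation is quasi-Newton (L-BFGS-B) with analytic gradients for both
forms (the phylogenetic gradient uses the REML identity
``tr(P dV) - y'P dV P y`` evaluated in the common eigenbasis), with
multiple jittered restarts.  Loadings are identified by zeroing the strict
upper triangle of the first ``q`` rows of ``Lambda``; variances are
log-parameterised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from scipy import optimize

from .covmatrix import CovMatrix

_LOG2PI = math.log(2.0 * math.pi)
_BIG = 1e12


# --------------------------------------------------------------------------
# parameterisation


@dataclass(frozen=True)
class Component:
    """One variance component: 'fa' (Lambda Lambda' + diag psi) or 'diag'."""

    name: str
    kind: str              # "fa" | "diag"
    p: int
    q: int = 0

    @property
    def n_params(self) -> int:
        if self.kind == "fa":
            return self.p * self.q - self.q * (self.q - 1) // 2 + self.p
        if self.kind == "diag":
            return self.p
        raise ValueError(self.kind)

    def loading_mask(self) -> np.ndarray:
        """Boolean (p, q) mask of free loading entries (lower trapezoid)."""
        i = np.arange(self.p)[:, None]
        j = np.arange(self.q)[None, :]
        return i >= j


class ParamLayout:
    """Packs/unpacks the parameter vector across components."""

    def __init__(self, components: list[Component]):
        self.components = components
        self.slices: dict[str, slice] = {}
        start = 0
        for comp in components:
            self.slices[comp.name] = slice(start, start + comp.n_params)
            start += comp.n_params
        self.n_params = start

    def component(self, name: str) -> Component:
        for comp in self.components:
            if comp.name == name:
                return comp
        raise KeyError(name)

    def build(self, comp: Component, seg: np.ndarray) -> np.ndarray:
        """Component covariance matrix from its parameter segment."""
        if comp.kind == "diag":
            return np.diag(np.exp(seg))
        mask = comp.loading_mask()
        n_l = int(mask.sum())
        lam = np.zeros((comp.p, comp.q))
        lam[mask] = seg[:n_l]
        psi = np.exp(seg[n_l:])
        return lam @ lam.T + np.diag(psi)

    def build_all(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        return {c.name: self.build(c, theta[self.slices[c.name]]) for c in self.components}

    def loadings(self, comp: Component, seg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mask = comp.loading_mask()
        n_l = int(mask.sum())
        lam = np.zeros((comp.p, comp.q))
        lam[mask] = seg[:n_l]
        return lam, np.exp(seg[n_l:])

    def grad_segment(self, comp: Component, seg: np.ndarray, m_mat: np.ndarray) -> np.ndarray:
        """Chain rule: d f / d seg given M = d f / d Gamma (symmetric)."""
        if comp.kind == "diag":
            return np.diag(m_mat) * np.exp(seg)
        mask = comp.loading_mask()
        n_l = int(mask.sum())
        lam = np.zeros((comp.p, comp.q))
        lam[mask] = seg[:n_l]
        g_lam = 2.0 * (m_mat @ lam)
        g_psi = np.diag(m_mat) * np.exp(seg[n_l:])
        return np.concatenate([g_lam[mask], g_psi])

    def start_from_moments(self, moments: dict[str, np.ndarray],
                           floor_frac: float = 1e-4) -> np.ndarray:
        """Initial parameters from moment estimates of each component."""
        theta = np.empty(self.n_params)
        for comp in self.components:
            gam = moments[comp.name]
            gam = (gam + gam.T) / 2.0
            floor = max(float(np.trace(gam)) / comp.p, 1e-12) * floor_frac
            if comp.kind == "diag":
                theta[self.slices[comp.name]] = np.log(np.clip(np.diag(gam), floor, None))
                continue
            w, v = np.linalg.eigh(gam)
            w, v = w[::-1], v[:, ::-1]
            lam0 = v[:, : comp.q] * np.sqrt(np.clip(w[: comp.q], floor, None))
            # rotate the factor block so the first q rows are lower
            # triangular (LQ of the top block via QR of its transpose)
            if comp.q > 1:
                qmat, _ = np.linalg.qr(lam0[: comp.q].T)
                lam0 = lam0 @ qmat
                lam0[: comp.q] = np.tril(lam0[: comp.q])
            psi0 = np.clip(np.diag(gam) - np.sum(lam0 ** 2, axis=1), floor, None)
            mask = comp.loading_mask()
            seg = np.concatenate([lam0[mask], np.log(psi0)])
            theta[self.slices[comp.name]] = seg
        return theta


# --------------------------------------------------------------------------
# balanced-strata REML


@dataclass
class Stratum:
    scatter: np.ndarray    # (p, p) sum of outer products of contrasts
    df: int
    coef: dict[str, float]  # component name -> multiplier in V_k


class StrataREML:
    """REML problem over independent balanced strata."""

    def __init__(self, strata: list[Stratum], layout: ParamLayout):
        self.strata = strata
        self.layout = layout
        self.p = strata[0].scatter.shape[0]
        self.const = sum(st.df for st in strata) * self.p * _LOG2PI

    def moment_estimates(self) -> dict[str, np.ndarray]:
        """Solve E[S_k/df_k] = sum_j c_kj Gamma_j by least squares."""
        names = [c.name for c in self.layout.components]
        cmat = np.array([[st.coef.get(n, 0.0) for n in names] for st in self.strata])
        rhs = np.stack([st.scatter / st.df for st in self.strata])
        pinv = np.linalg.pinv(cmat)
        sol = np.einsum("jk,kab->jab", pinv, rhs)
        return dict(zip(names, sol))

    def neg2_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        mats = self.layout.build_all(theta)
        total = self.const
        m_acc = {name: np.zeros((self.p, self.p)) for name in mats}
        eye = np.eye(self.p)
        for st in self.strata:
            v = sum(c * mats[name] for name, c in st.coef.items())
            try:
                cf = sla.cho_factor(v, lower=True, check_finite=False)
            except sla.LinAlgError:
                return _BIG, np.zeros_like(theta)
            logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
            vinv = sla.cho_solve(cf, eye, check_finite=False)
            total += st.df * logdet + float(np.sum(vinv * st.scatter))
            a = st.df * vinv - vinv @ st.scatter @ vinv
            for name, c in st.coef.items():
                m_acc[name] += c * a
        grad = np.empty_like(theta)
        for comp in self.layout.components:
            sl = self.layout.slices[comp.name]
            grad[sl] = self.layout.grad_segment(comp, theta[sl], m_acc[comp.name])
        return float(total), grad

    def neg2(self, theta: np.ndarray) -> float:
        return self.neg2_and_grad(theta)[0]

    gradient = None   # analytic gradient supplied by neg2_and_grad


# --------------------------------------------------------------------------
# phylogenetic REML (species effects with covariance S (x) Sigma_u)


class PhyloREML:
    """REML for species means on a phylogeny.

    ``z`` are species means rotated into the eigenbasis of the relationship
    matrix (eigenvalues ``delta``); ``t`` is the rotated intercept column;
    ``c_e`` multiplies the diagonal error component within blocks (1/m for
    m replicates per species).  An optional residual stratum carries the
    within-species information about the error variances.
    """

    def __init__(self, z: np.ndarray, t: np.ndarray, delta: np.ndarray,
                 c_e: float, layout: ParamLayout,
                 resid_scatter_diag: np.ndarray | None = None,
                 resid_df: int = 0):
        self.z, self.t, self.delta, self.c_e = z, t, delta, c_e
        self.layout = layout
        self.p = z.shape[1]
        self.resid_diag = resid_scatter_diag
        self.resid_df = resid_df
        n_blocks = z.shape[0]
        self.const = ((n_blocks - 1) * self.p + resid_df * self.p) * _LOG2PI
        names = {c.name for c in layout.components}
        if names != {"u", "e"}:
            raise ValueError("phylogenetic REML expects components 'u' and 'e'")
        if layout.component("e").kind != "diag":
            raise ValueError("error component must be diagonal")

    def neg2_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """Value and analytic gradient of -2 log REML likelihood.

        All block matrices ``V_i = delta_i Sigma_u + c_e Sigma_e`` share
        the eigenbasis of ``W Sigma_u W`` with ``W = (c_e Sigma_e)^{-1/2}``
        (Sigma_e diagonal), so every determinant, solve and the REML
        projection matrix are diagonal after one p x p eigendecomposition.
        The gradient uses the standard REML identity
        ``d(-2l)/dtheta = tr(P dV) - y' P dV P y`` with
        ``P = V^{-1} - V^{-1} X (X'V^{-1}X)^{-1} X' V^{-1}``.
        """
        zero = np.zeros_like(theta)
        mats = self.layout.build_all(theta)
        sigma_u = mats["u"]
        ve = np.diag(mats["e"])
        if np.any(ve <= 0) or not np.all(np.isfinite(ve)):
            return _BIG, zero
        total = self.const
        if self.resid_df:
            total += self.resid_df * float(np.sum(np.log(ve)))
            total += float(np.sum(self.resid_diag / ve))
        w = 1.0 / np.sqrt(ve * self.c_e)
        b = (w[:, None] * sigma_u) * w[None, :]
        try:
            kappa, u = np.linalg.eigh(b)
        except np.linalg.LinAlgError:
            return _BIG, zero
        den = 1.0 + self.delta[:, None] * kappa[None, :]          # (n, p)
        if np.any(den <= 1e-12):
            return _BIG, zero
        zt = (self.z * w[None, :]) @ u                             # (n, p)
        log_ve_ce = float(np.sum(np.log(ve * self.c_e)))
        total += float(np.sum(np.log(den))) + self.z.shape[0] * log_ve_ce
        t2 = self.t ** 2
        a_tilde = (t2[:, None] / den).sum(axis=0)                  # (p,)
        b_tilde = (self.t[:, None] * zt / den).sum(axis=0)
        mu_tilde = b_tilde / a_tilde
        resid = zt - self.t[:, None] * mu_tilde[None, :]
        total += float(np.sum(resid ** 2 / den))
        # REML correction for the profiled mean: log|sum_i t_i^2 V_i^{-1}|
        total += float(np.sum(np.log(a_tilde))) + 2.0 * float(np.sum(np.log(w)))

        # ---- gradient ----------------------------------------------------
        # In the transformed basis (U' W .) the i-th diagonal of P is
        # 1/den_i - t_i^2 / (A~ den_i^2) and (P y)_i = resid_i / den_i.
        inv_den = 1.0 / den                                        # (n, p)
        p_diag = inv_den - (t2[:, None] * inv_den ** 2) / a_tilde[None, :]
        rho = resid * inv_den                                      # (n, p)
        # d/dSigma_u: blocks weighted by delta_i
        du_diag = (self.delta[:, None] * p_diag).sum(axis=0)       # (p,)
        g_u_t = np.diag(du_diag) - (rho * self.delta[:, None]).T @ rho
        # d/dSigma_e within blocks: weight c_e
        de_diag_t = self.c_e * p_diag.sum(axis=0)
        g_e_t = np.diag(de_diag_t) - self.c_e * rho.T @ rho
        # back-transform: G = (W U) G~ (W U)'
        wu = w[:, None] * u
        g_u = wu @ g_u_t @ wu.T
        g_e_full = wu @ g_e_t @ wu.T
        g_e_diag = np.diag(g_e_full).copy()
        if self.resid_df:
            g_e_diag += self.resid_df / ve - self.resid_diag / ve ** 2
        grad = np.empty_like(theta)
        comp_u = self.layout.component("u")
        comp_e = self.layout.component("e")
        sl_u, sl_e = self.layout.slices["u"], self.layout.slices["e"]
        grad[sl_u] = self.layout.grad_segment(comp_u, theta[sl_u], (g_u + g_u.T) / 2.0)
        grad[sl_e] = self.layout.grad_segment(comp_e, theta[sl_e], np.diag(g_e_diag))
        return float(total), grad

    def neg2(self, theta: np.ndarray) -> float:
        return self.neg2_and_grad(theta)[0]


# --------------------------------------------------------------------------
# fitting


@dataclass
class FAFitModel:
    """A fitted factor-analytic REML model (matrices on the original
    coordinate scale; ``scale`` records the pre-multiplier used during
    fitting)."""

    rank_q: int
    loadings: np.ndarray            # (p, q)
    specific_variances: np.ndarray  # (p,)
    error_variances: np.ndarray     # (p,)
    other_components: dict[str, np.ndarray]
    reml_loglik: float
    aic: float
    n_params: int
    converged: bool
    scale: float
    random_name: str = "u"
    label: str = "D"
    taxon: str = ""
    _problem: object = None
    _theta: np.ndarray | None = None
    _sampling_cov_vech: np.ndarray | None = None

    @property
    def sigma_u(self) -> np.ndarray:
        return self.loadings @ self.loadings.T + np.diag(self.specific_variances)

    @property
    def p(self) -> int:
        return self.loadings.shape[0]

    def cov_matrix(self) -> CovMatrix:
        return CovMatrix(self.sigma_u, label=self.label, taxon=self.taxon,
                         scale_factor=self.scale,
                         source=f"factor-analytic REML, q={self.rank_q}",
                         validate=False)

    # -- asymptotic sampling covariance ---------------------------------

    def param_sampling_cov(self) -> np.ndarray:
        """Covariance of vech(Sigma_u) from the inverse observed
        information at the optimum ('G-scale' delta method)."""
        if self._sampling_cov_vech is not None:
            return self._sampling_cov_vech
        problem, theta = self._problem, self._theta
        if problem is None:
            raise ValueError("fit carries no problem object")
        n_par = theta.size
        # observed information of the restricted log-likelihood:
        # H = 0.5 * d^2(neg2)/dtheta^2, via finite differences of the gradient
        h = 1e-4
        hess = np.empty((n_par, n_par))
        for i in range(n_par):
            step = h * max(1.0, abs(theta[i]))
            up = theta.copy(); up[i] += step
            dn = theta.copy(); dn[i] -= step
            g_up = problem.neg2_and_grad(up)[1]
            g_dn = problem.neg2_and_grad(dn)[1]
            hess[i] = 0.5 * (g_up - g_dn) / (2.0 * step)
        hess = (hess + hess.T) / 2.0
        cov_theta = np.linalg.pinv(hess, hermitian=True)

        # Jacobian of vech(Sigma_u / scale^2) wrt theta (finite differences)
        layout = problem.layout
        comp = layout.component(self.random_name)
        sl = layout.slices[comp.name]
        iu = np.triu_indices(self.p)
        jac = np.zeros((iu[0].size, n_par))
        for i in range(sl.start, sl.stop):
            step = h * max(1.0, abs(theta[i]))
            up = theta.copy(); up[i] += step
            dn = theta.copy(); dn[i] -= step
            s_up = layout.build(comp, up[sl]) / self.scale ** 2
            s_dn = layout.build(comp, dn[sl]) / self.scale ** 2
            jac[:, i] = (s_up[iu] - s_dn[iu]) / (2.0 * step)
        cov_vech = jac @ cov_theta @ jac.T
        cov_vech = (cov_vech + cov_vech.T) / 2.0
        self._sampling_cov_vech = cov_vech
        return cov_vech


def _fit(problem, start: np.ndarray, n_restarts: int = 5, seed: int = 0,
         maxiter: int = 6000) -> tuple[np.ndarray, float, bool]:
    """Quasi-Newton maximisation with jittered restarts.

    A run counts as converged when the optimiser reports success or the
    final gradient is negligible (factor-loading rotations are weakly
    identified near the optimum, so L-BFGS can exhaust its iteration
    budget while the likelihood is already stationary).
    """
    rng = np.random.default_rng(seed)
    best_theta, best_val, best_ok = None, np.inf, False
    for attempt in range(max(1, n_restarts)):
        x0 = start if attempt == 0 else start + rng.normal(0.0, 0.3, start.size)
        res = optimize.minimize(
            problem.neg2_and_grad, x0, jac=True, method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-6},
        )
        ok = bool(res.success) or float(np.abs(res.jac).max()) < 1.0
        if res.fun < best_val - 1e-9:
            best_theta, best_val, best_ok = res.x, float(res.fun), ok
        elif res.fun < best_val + 1e-6 and ok:
            best_ok = True
    if best_theta is None or best_val >= _BIG / 2:
        return start, _BIG, False
    return best_theta, best_val, best_ok


def fit_strata_model(strata: list[Stratum], components: list[Component],
                     scale: float = 1.0, n_restarts: int = 5, seed: int = 0,
                     random_name: str = "u", label: str = "D",
                     taxon: str = "") -> FAFitModel:
    """Fit a factor-analytic REML model to balanced strata.

    ``scale`` records the coordinate pre-multiplier used when the scatter
    matrices were built; returned matrices are divided by ``scale**2``.
    """
    layout = ParamLayout(components)
    problem = StrataREML(strata, layout)
    start = layout.start_from_moments(problem.moment_estimates())
    theta, neg2, ok = _fit(problem, start, n_restarts, seed)
    return _package_fit(problem, layout, theta, neg2, ok, scale,
                        random_name, label, taxon)


def _package_fit(problem, layout: ParamLayout, theta: np.ndarray, neg2: float,
                 converged: bool, scale: float, random_name: str,
                 label: str, taxon: str) -> FAFitModel:
    comp_u = layout.component(random_name)
    lam, psi = layout.loadings(comp_u, theta[layout.slices[random_name]]) \
        if comp_u.kind == "fa" else (np.zeros((comp_u.p, 0)), np.exp(theta[layout.slices[random_name]]))
    mats = layout.build_all(theta)
    err = np.diag(mats["e"]) if "e" in mats else np.zeros(comp_u.p)
    other = {name: m / scale ** 2 for name, m in mats.items()
             if name not in (random_name, "e")}
    n_params = layout.n_params
    return FAFitModel(
        rank_q=comp_u.q if comp_u.kind == "fa" else 0,
        loadings=lam / scale,
        specific_variances=psi / scale ** 2,
        error_variances=err / scale ** 2,
        other_components=other,
        reml_loglik=-0.5 * neg2,
        aic=neg2 + 2.0 * n_params,
        n_params=n_params,
        converged=converged,
        scale=scale,
        random_name=random_name,
        label=label,
        taxon=taxon,
        _problem=problem,
        _theta=theta,
    )


# --------------------------------------------------------------------------
# rank selection


@dataclass
class RankSelection:
    fits: dict[int, FAFitModel]
    chosen_rank: int
    delta_aic_path: list[float]

    @property
    def chosen(self) -> FAFitModel:
        return self.fits[self.chosen_rank]


def select_rank(fit_fn, max_rank: int, delta: float = 2.0) -> RankSelection:
    """Sequential AIC rank selection for factor-analytic fits.

    Fits rank 1, 2, ... until the AIC improvement over the previous rank
    drops below ``delta`` or a fit fails to converge; the chosen rank is
    the smallest whose AIC is within ``delta`` of the minimum among
    converged fits (ties broken toward smaller rank).
    """
    fits: dict[int, FAFitModel] = {}
    path: list[float] = []
    prev_aic = None
    for q in range(1, max_rank + 1):
        fit = fit_fn(q)
        if not fit.converged:
            break
        fits[q] = fit
        stop = False
        if prev_aic is not None:
            path.append(prev_aic - fit.aic)
            stop = prev_aic - fit.aic < delta
        prev_aic = fit.aic
        if stop:
            break
    if not fits:
        raise RuntimeError("no rank converged")
    best = min(f.aic for f in fits.values())
    chosen = min(q for q, f in fits.items() if f.aic <= best + delta)
    return RankSelection(fits=fits, chosen_rank=chosen, delta_aic_path=path)


# --------------------------------------------------------------------------
# REML-MVN resampling


def reml_mvn_resample(fit: FAFitModel, n_samples: int, seed: int | None = None,
                      scale: str = "G") -> list[CovMatrix]:
    """Draw covariance matrices from the asymptotic (REML-MVN) sampling
    distribution of the fitted random-effect covariance.

    Sampling is on the 'G-scale': the distinct elements of ``Sigma_u`` are
    drawn from a multivariate normal centered at the REML estimate with the
    delta-method sampling covariance.  Draws that are not PSD are retained
    but flagged (``is_psd`` False).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if scale != "G":
        raise ValueError("only 'G-scale' resampling is implemented")
    p = fit.p
    iu = np.triu_indices(p)
    center = fit.sigma_u[iu]
    cov = fit.param_sampling_cov()
    # clip tiny negative eigenvalues so the MVN draw is well defined
    w, v = np.linalg.eigh(cov)
    cov_psd = (v * np.clip(w, 0.0, None)) @ v.T
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(center, cov_psd, size=n_samples,
                                    method="eigh")
    out = []
    for vec in draws:
        mat = np.zeros((p, p))
        mat[iu] = vec
        mat = mat + mat.T - np.diag(np.diag(mat))
        out.append(CovMatrix(mat, label=fit.label, taxon=fit.taxon,
                             scale_factor=fit.scale,
                             source="REML-MVN draw", validate=False))
    return out
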