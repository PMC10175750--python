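"""Mixed-model designs for D, P, G and R estimation.

Each estimator maps an :class:`~devbias.align.AlignedDataset` onto the
balanced-strata (or phylogenetic) REML machinery in :mod:`devbias.reml`:

* **D** — fixed individual and side, random individual-by-side (FA),
  replicate measurements as error.
* **P** — fixed side (directional asymmetry), random individual.
* **G** — fixed sex and rearing temperature, random isofemale line
  (population random when line counts are balanced across populations,
  otherwise absorbed as a fixed effect so the strata stay exact).
* **R** — random species whose covariance is ``S (x) Sigma_u`` with ``S``
  the phylogenetic relationship matrix; the Brownian-motion rate matrix
  ``Sigma_u`` is returned.

Coordinates are multiplied by ``scale`` (default 10,000) before fitting to
keep the optimiser well conditioned; all returned matrices are rescaled to
original units.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .align import AlignedDataset
from .covmatrix import CovMatrix
from .phylo import RelationshipMatrix
from .reml import (Component, FAFitModel, ParamLayout, PhyloREML, Stratum,
                   StrataREML, _fit, _package_fit, fit_strata_model)


def sample_covariance(deviations: np.ndarray, divisor: str = "n-1",
                      label: str = "D", taxon: str = "") -> CovMatrix:
    """Plain sample covariance of an (n, p) deviation matrix."""
    x = np.asarray(deviations, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need an (n >= 2, p) deviation matrix")
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    denom = n if divisor == "n" else n - 1
    return CovMatrix((xc.T @ xc) / denom, label=label, taxon=taxon,
                     source=f"sample covariance (divisor {divisor})",
                     validate=False)


# --------------------------------------------------------------------------
# strata builders


def _fa_strata(y: np.ndarray, fac: pd.DataFrame) -> list[Stratum]:
    """Interaction + error strata for the FA (D) design."""
    individuals = pd.Index(pd.unique(fac["individual"]))
    ind = individuals.get_indexer(fac["individual"])
    s_idx = (fac["side"].to_numpy() == "right").astype(int)
    n_ind, p = len(individuals), y.shape[1]
    sizes = fac.groupby(["individual", "side"], sort=False).size()
    if sizes.nunique() != 1 or set(fac["side"]) != {"left", "right"}:
        raise ValueError("FA design must be balanced with both sides per individual")
    m = int(sizes.iloc[0])

    cell = np.zeros((n_ind, 2, p))
    np.add.at(cell, (ind, s_idx), y)
    cell /= m
    ind_mean = cell.mean(axis=1)
    side_mean = cell.mean(axis=0)
    grand = ind_mean.mean(axis=0)
    f = cell - ind_mean[:, None, :] - side_mean[None, :, :] + grand
    ss_int = m * np.einsum("isa,isb->ab", f, f)
    err = y - cell[ind, s_idx]
    ss_err = err.T @ err
    df_int = (n_ind - 1)
    df_err = n_ind * 2 * (m - 1)
    strata = [Stratum(ss_int, df_int, {"u": float(m), "e": 1.0})]
    if df_err > 0:
        strata.append(Stratum(ss_err, df_err, {"e": 1.0}))
    return strata


def _individual_strata(y: np.ndarray, fac: pd.DataFrame) -> list[Stratum]:
    """Between-individual + residual strata for the P design (side fixed)."""
    individuals = pd.Index(pd.unique(fac["individual"]))
    ind = individuals.get_indexer(fac["individual"])
    n_ind = len(individuals)
    counts = np.bincount(ind, minlength=n_ind).astype(float)
    if counts.std() > 1e-9:
        raise ValueError("P design must be balanced (equal observations per individual)")
    r = float(counts[0])
    ind_mean = np.zeros((n_ind, y.shape[1]))
    np.add.at(ind_mean, ind, y)
    ind_mean /= r
    grand = y.mean(axis=0)
    dev = ind_mean - grand
    ss_between = r * dev.T @ dev
    # residual: remove individual means and the fixed side effect
    resid = y - ind_mean[ind]
    n_fixed = 1
    if "side" in fac.columns and fac["side"].nunique() > 1:
        sides = pd.Index(pd.unique(fac["side"]))
        s_idx = sides.get_indexer(fac["side"])
        side_mean = np.zeros((len(sides), y.shape[1]))
        np.add.at(side_mean, s_idx, resid)
        side_mean /= np.bincount(s_idx)[:, None]
        resid = resid - side_mean[s_idx]
        n_fixed = len(sides)
    ss_resid = resid.T @ resid
    df_resid = y.shape[0] - n_ind - (n_fixed - 1)
    return [
        Stratum(ss_between, n_ind - 1, {"u": r, "e": 1.0}),
        Stratum(ss_resid, df_resid, {"e": 1.0}),
    ]


def _line_strata(y: np.ndarray, fac: pd.DataFrame,
                 population_random: bool | None = None
                 ) -> tuple[list[Stratum], bool]:
    """Line (and optionally population) strata for the G design.

    Fixed effects: sex and rearing temperature (as a factor).  When line
    counts per population are unequal the population term is absorbed as a
    fixed effect instead of estimated as a random component, which keeps
    the balanced-strata REML exact; the line-level matrix is unaffected in
    expectation.
    """
    for col in ("line",):
        if col not in fac.columns:
            raise ValueError("G design requires a 'line' factor column")
    lines = pd.Index(pd.unique(fac["line"]))
    l_idx = lines.get_indexer(fac["line"])
    n_lines, p = len(lines), y.shape[1]
    per_line = np.bincount(l_idx, minlength=n_lines).astype(float)
    if per_line.std() > 1e-9:
        raise ValueError("G design must be balanced (equal observations per line)")
    m = float(per_line[0])

    has_pop = "population" in fac.columns
    if has_pop:
        pops = pd.Index(pd.unique(fac["population"]))
        pop_of_line = fac.groupby("line", sort=False)["population"].first()
        lines_per_pop = pop_of_line.groupby(pop_of_line).size()
        balanced_pops = lines_per_pop.nunique() == 1 and len(pops) > 1
    else:
        balanced_pops = False
    if population_random is None:
        population_random = balanced_pops
    if population_random and not balanced_pops:
        warnings.warn("unequal line counts per population: population "
                      "treated as a fixed effect", stacklevel=2)
        population_random = False

    line_mean = np.zeros((n_lines, p))
    np.add.at(line_mean, l_idx, y)
    line_mean /= m

    strata: list[Stratum] = []
    if population_random:
        n_per_pop = lines_per_pop.iloc[0]
        p_idx = pops.get_indexer(fac["population"])
        pop_mean = np.zeros((len(pops), p))
        np.add.at(pop_mean, p_idx, y)
        pop_mean /= np.bincount(p_idx)[:, None]
        grand = y.mean(axis=0)
        dev_p = pop_mean - grand
        ss_pop = m * n_per_pop * dev_p.T @ dev_p
        strata.append(Stratum(ss_pop, len(pops) - 1,
                              {"pop": m * n_per_pop, "u": m, "e": 1.0}))
        pop_of_line_idx = pops.get_indexer(pop_of_line.loc[lines])
        dev_l = line_mean - pop_mean[pop_of_line_idx]
        df_line = n_lines - len(pops)
    else:
        if has_pop:
            pop_of_line_idx = pops.get_indexer(pop_of_line.loc[lines])
            pop_mean_l = np.zeros((len(pops), p))
            np.add.at(pop_mean_l, pop_of_line_idx, line_mean)
            pop_mean_l /= np.bincount(pop_of_line_idx)[:, None]
            dev_l = line_mean - pop_mean_l[pop_of_line_idx]
            df_line = n_lines - len(pops)
        else:
            dev_l = line_mean - line_mean.mean(axis=0)
            df_line = n_lines - 1
    ss_line = m * dev_l.T @ dev_l
    strata.append(Stratum(ss_line, df_line, {"u": m, "e": 1.0}))

    # residual: remove line means and the fixed sex/temperature effects
    resid = y - line_mean[l_idx]
    df_fixed = 0
    for col in ("sex", "temperature_C"):
        if col in fac.columns and fac[col].nunique() > 1:
            levels = pd.Index(pd.unique(fac[col]))
            c_idx = levels.get_indexer(fac[col])
            eff = np.zeros((len(levels), p))
            np.add.at(eff, c_idx, resid)
            eff /= np.bincount(c_idx)[:, None]
            resid = resid - eff[c_idx]
            df_fixed += len(levels) - 1
    ss_resid = resid.T @ resid
    df_resid = y.shape[0] - n_lines - df_fixed
    strata.append(Stratum(ss_resid, df_resid, {"e": 1.0}))
    return strata, population_random


# --------------------------------------------------------------------------
# public fitting interface


_DESIGNS = {"D": "individual:side", "P": "individual", "G": "line"}


def fit_factor_analytic(data: AlignedDataset, design: str | dict, rank_q: int,
                        scale: float = 10000.0, n_restarts: int = 5,
                        seed: int = 0, taxon: str = "") -> FAFitModel:
    """Factor-analytic REML fit of one of the standard designs.

    Parameters
    ----------
    data : aligned dataset whose ``factors`` carry the design columns.
    design : 'D', 'P' or 'G' (or a dict with a ``random`` key equal to
        'individual:side', 'individual' or 'line').
    rank_q : number of factor columns (0 fits a diagonal-only covariance).
    scale : coordinate pre-multiplier easing convergence (default 10,000).
    """
    if isinstance(design, dict):
        random_term = design.get("random")
        label = {v: k for k, v in _DESIGNS.items()}.get(random_term)
        if label is None:
            raise ValueError(f"unrecognised random term {random_term!r}")
    else:
        label = design
        if label not in _DESIGNS:
            raise ValueError(f"design must be one of {sorted(_DESIGNS)}")
    if rank_q < 0:
        raise ValueError("rank_q must be >= 0")

    y = data.shape_coords * scale
    fac = data.factors
    p = y.shape[1]
    u_comp = Component("u", "fa", p, rank_q) if rank_q > 0 else Component("u", "diag", p)
    components = [u_comp, Component("e", "diag", p)]

    if label == "D":
        strata = _fa_strata(y, fac)
    elif label == "P":
        strata = _individual_strata(y, fac)
    else:
        strata, pop_random = _line_strata(y, fac)
        if pop_random:
            components.insert(1, Component("pop", "diag", p))
    fit = fit_strata_model(strata, components, scale=scale,
                           n_restarts=n_restarts, seed=seed,
                           random_name="u", label=label if label != "D" else "D",
                           taxon=taxon)
    return fit


def estimate_R(data: AlignedDataset, relationship: RelationshipMatrix,
               rank_q: int, scale: float = 10000.0, n_restarts: int = 3,
               seed: int = 0, taxon: str = "") -> FAFitModel:
    """Estimate the Brownian-motion rate matrix R by phylogenetic REML.

    Species effects have covariance ``S (x) Sigma_u``; the within-species
    residual has a separate diagonal variance per shape variable.  Requires
    the same number of measured wings per species (species means carry the
    phylogenetic information; the residual stratum calibrates the error).
    """
    fac = data.factors
    if "species" not in fac.columns:
        raise ValueError("R design requires a 'species' factor column")
    species = pd.Index(relationship.taxa)
    present = pd.Index(pd.unique(fac["species"]))
    missing = set(species) - set(present)
    if missing:
        raise ValueError(f"species in relationship matrix without data: {sorted(missing)}")
    if len(present) < 3:
        raise ValueError("need at least three species")
    y = data.shape_coords * scale
    sp_idx = species.get_indexer(fac["species"])
    n_sp, p = len(species), y.shape[1]
    counts = np.bincount(sp_idx, minlength=n_sp).astype(float)
    if counts.min() < 1:
        raise ValueError("every species needs at least one observation")
    if counts.std() > 1e-9:
        raise ValueError("phylogenetic REML requires equal replicates per species")
    m = float(counts[0])
    means = np.zeros((n_sp, p))
    np.add.at(means, sp_idx, y)
    means /= m
    resid = y - means[sp_idx]
    resid_diag = np.sum(resid ** 2, axis=0)
    df_resid = int(y.shape[0] - n_sp)

    w, q = np.linalg.eigh(relationship.S)
    delta = np.clip(w, 0.0, None)
    z = q.T @ means
    t = q.T @ np.ones(n_sp)

    u_comp = Component("u", "fa", p, rank_q) if rank_q > 0 else Component("u", "diag", p)
    layout = ParamLayout([u_comp, Component("e", "diag", p)])
    problem = PhyloREML(z, t, delta, 1.0 / m, layout,
                        resid_scatter_diag=resid_diag, resid_df=df_resid)

    # moment start: among-species covariance scaled by mean tree depth
    dev = means - means.mean(axis=0)
    depth = float(np.mean(np.diag(relationship.S)))
    moment_u = (dev.T @ dev) / max(n_sp - 1, 1) / max(depth, 1e-6)
    moment_e = np.diag(resid_diag / max(df_resid, 1)) if df_resid else np.eye(p) * moment_u.trace() / p * 0.01
    start = layout.start_from_moments({"u": moment_u, "e": moment_e})
    theta, neg2, ok = _fit(problem, start, n_restarts, seed)
    return _package_fit(problem, layout, theta, neg2, ok, scale,
                        "u", "R", taxon)
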