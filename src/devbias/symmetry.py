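"""Bilateral-symmetry decomposition and Procrustes ANOVA.

For a matching-symmetry design (individuals x sides x replicate
measurements, left side reflected before joint alignment) the aligned
coordinates decompose by least squares into

* a symmetric component (individual means),
* directional asymmetry (the mean right-minus-left offset),
* fluctuating asymmetry (the individual-by-side interaction), and
* measurement error (replicate residuals).

The FA deviation stored per individual is the signed half left-right
contrast adjusted for directional asymmetry, i.e. the interaction effect
attributed to the right side.  The developmental matrix D is defined as the
covariance of ONE side's FA effect; `estimate_D` applies the moment
correction (MS_interaction - MS_error)/m that makes the estimator unbiased
for that per-side covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .align import AlignedDataset
from .covmatrix import CovMatrix


@dataclass
class SymmetryComponents:
    """Least-squares decomposition of an FA design."""

    individuals: np.ndarray            # (n_ind,) labels
    grand_mean: np.ndarray             # (p,)
    symmetric_component: np.ndarray    # (n_ind, p) individual means - grand
    directional_asymmetry: np.ndarray  # (p,) mean right - left offset
    fa_deviation: np.ndarray           # (n_ind, p) half signed L/R contrast, DA-adjusted
    error_deviation: np.ndarray        # (n_obs, p)
    obs_individual_index: np.ndarray   # (n_obs,) row into individuals
    obs_side_sign: np.ndarray          # (n_obs,) +1 right, -1 left
    n_replicates: int
    n_excluded: int = 0
    antisymmetry_excess_kurtosis: float = float("nan")
    antisymmetry_p: float = float("nan")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def reconstruct(self) -> np.ndarray:
        """Rebuild the aligned observations from the components (exact)."""
        ind = self.obs_individual_index
        sign = self.obs_side_sign[:, None]
        return (
            self.grand_mean
            + self.symmetric_component[ind]
            + sign * (self.directional_asymmetry / 2.0)
            + sign * self.fa_deviation[ind]
            + self.error_deviation
        )


def bilateral_decompose(aligned: AlignedDataset) -> SymmetryComponents:
    """Decompose aligned FA data into symmetric, directional-asymmetry,
    FA and measurement-error components.

    Requires factor columns ``individual``, ``side`` and ``measurement``;
    individuals with only one side measured are excluded with a warning.
    """
    fac = aligned.factors
    for col in ("individual", "side", "measurement"):
        if col not in fac.columns:
            raise ValueError(f"factor column {col!r} required for bilateral decomposition")
    sides = set(fac["side"])
    if not sides <= {"left", "right"}:
        raise ValueError("sides must be 'left'/'right' for a matching-symmetry design")

    y = aligned.shape_coords
    per_ind_sides = fac.groupby("individual", sort=False)["side"].nunique()
    complete = per_ind_sides[per_ind_sides == 2].index
    n_excluded = int((per_ind_sides != 2).sum())
    if n_excluded:
        warnings.warn(
            f"excluded {n_excluded} individual(s) with only one side measured",
            stacklevel=2,
        )
    keep = fac["individual"].isin(complete).to_numpy()
    fac = fac.loc[keep].reset_index(drop=True)
    y = y[keep]

    cell_sizes = fac.groupby(["individual", "side"], sort=False).size()
    if cell_sizes.nunique() != 1:
        raise ValueError("unbalanced replicate counts per (individual, side) cell")
    m = int(cell_sizes.iloc[0])

    individuals = pd.Index(pd.unique(fac["individual"]))
    ind_idx = individuals.get_indexer(fac["individual"])
    side_sign = np.where(fac["side"].to_numpy() == "right", 1.0, -1.0)
    n_ind, p = len(individuals), y.shape[1]

    grand = y.mean(axis=0)
    # cell means (individual x side)
    cell_mean = np.zeros((n_ind, 2, p))
    counts = np.zeros((n_ind, 2))
    s_idx = (side_sign > 0).astype(int)          # 0 = left, 1 = right
    np.add.at(cell_mean, (ind_idx, s_idx), y)
    np.add.at(counts, (ind_idx, s_idx), 1.0)
    cell_mean /= counts[:, :, None]

    ind_mean = cell_mean.mean(axis=1)
    side_mean = cell_mean.mean(axis=0)           # (2, p): left, right
    da = side_mean[1] - side_mean[0]

    symmetric = ind_mean - grand
    # interaction effect attributed to the right side
    fa = (cell_mean[:, 1] - cell_mean[:, 0] - da) / 2.0
    error = y - cell_mean[ind_idx, s_idx]

    # antisymmetry diagnostic: excess kurtosis of the signed asymmetry
    # projected on its first principal axis (negative excess kurtosis
    # suggests bimodality, i.e. antisymmetry); reported, never gating
    signed = cell_mean[:, 1] - cell_mean[:, 0]
    signed_c = signed - signed.mean(axis=0)
    if n_ind > 3:
        _, _, vt = np.linalg.svd(signed_c, full_matrices=False)
        proj = signed_c @ vt[0]
        kurt = float(stats.kurtosis(proj, fisher=True, bias=False))
        try:
            kurt_p = float(stats.kurtosistest(proj).pvalue) if n_ind >= 20 else float("nan")
        except ValueError:
            kurt_p = float("nan")
    else:
        kurt, kurt_p = float("nan"), float("nan")

    return SymmetryComponents(
        individuals=np.asarray(individuals),
        grand_mean=grand,
        symmetric_component=symmetric,
        directional_asymmetry=da,
        fa_deviation=fa,
        error_deviation=error,
        obs_individual_index=ind_idx,
        obs_side_sign=side_sign,
        n_replicates=m,
        n_excluded=n_excluded,
        antisymmetry_excess_kurtosis=kurt,
        antisymmetry_p=kurt_p,
    )


def procrustes_anova(components: SymmetryComponents) -> pd.DataFrame:
    """Procrustes ANOVA for a matching-symmetry design.

    Sums of squares are summed over all shape coordinates; degrees of
    freedom are the univariate design df (Goodall-style F).  The
    individual-by-side interaction (fluctuating asymmetry) is tested
    against the replicate-measurement error; the individual and side main
    effects are tested against the interaction.
    """
    n = components.n_individuals
    m = components.n_replicates
    n_sides = 2
    ss_ind = n_sides * m * float((components.symmetric_component ** 2).sum())
    ss_side = n * m * 2 * float(((components.directional_asymmetry / 2.0) ** 2).sum())
    ss_int = m * 2 * float((components.fa_deviation ** 2).sum())
    ss_err = float((components.error_deviation ** 2).sum())
    ss_total = ss_ind + ss_side + ss_int + ss_err

    df_ind = n - 1
    df_side = n_sides - 1
    df_int = (n - 1) * (n_sides - 1)
    df_err = n * n_sides * (m - 1)

    rows = {}
    ms_int = ss_int / df_int
    if df_err > 0 and ss_err > 0:
        ms_err = ss_err / df_err
        f_int = ms_int / ms_err
        p_int = float(stats.f.sf(f_int, df_int, df_err))
    elif df_err > 0:        # error-free replicates
        ms_err = 0.0
        f_int = float("inf") if ms_int > 0 else float("nan")
        p_int = 0.0 if ms_int > 0 else float("nan")
    else:
        ms_err, f_int, p_int = float("nan"), float("nan"), float("nan")
    def _main_effect(ss, df):
        ms = ss / df
        if ms_int > 0:
            f = ms / ms_int
            return ss, df, ms, f, float(stats.f.sf(f, df, df_int))
        return ss, df, ms, float("nan"), float("nan")

    rows["individual"] = _main_effect(ss_ind, df_ind)
    rows["side"] = _main_effect(ss_side, df_side)
    rows["individual_x_side"] = (ss_int, df_int, ms_int, f_int, p_int)
    rows["error"] = (ss_err, df_err, ms_err, float("nan"), float("nan"))

    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["SS", "df", "MS", "F", "p"]
    )
    table["eta_squared"] = table["SS"] / ss_total
    table.attrs["ss_total"] = ss_total
    return table


def estimate_D(components: SymmetryComponents, clip_negative: bool = True,
               taxon: str = "") -> CovMatrix:
    """Moment estimator of the developmental covariance matrix D.

    D is the covariance of one side's FA effect.  The interaction
    mean-square matrix has expectation ``Sigma_e + m * D``, so
    ``D_hat = (MS_int - MS_err) / m``.  Small negative eigenvalues from the
    error subtraction are clipped to zero by default.
    """
    n, m = components.n_individuals, components.n_replicates
    f = components.fa_deviation
    ms_int = (2.0 * m / (n - 1)) * (f.T @ f)
    df_err = n * 2 * (m - 1)
    if df_err > 0:
        e = components.error_deviation
        ms_err = (e.T @ e) / df_err
        d_hat = (ms_int - ms_err) / m
    else:
        d_hat = ms_int / m   # single replicate: error not separable
    d_hat = (d_hat + d_hat.T) / 2.0
    if clip_negative:
        w, v = np.linalg.eigh(d_hat)
        d_hat = (v * np.clip(w, 0.0, None)) @ v.T
        d_hat = (d_hat + d_hat.T) / 2.0
    return CovMatrix(matrix=d_hat, label="D", taxon=taxon,
                     source="moment estimator (Procrustes ANOVA)",
                     validate=False)
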