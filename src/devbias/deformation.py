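"""Shape-deformation vectors and their projection onto D.

Deformation vectors are partial regression coefficient vectors from
multivariate regressions of (averaged) shape on log centroid size, sex,
population, rearing temperature or latitude.  The amount of developmental
variance in the direction of a vector ``beta`` is the normalised quadratic
form ``e_beta = beta' D beta / (beta' beta)``; dividing by the trace of D
gives the proportion of total developmental variance captured.  A
randomization test reshuffles the entries of ``beta`` across coordinate
slots (preserving its length and entry distribution) to build the null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import AlignedDataset
from .covmatrix import CovMatrix

TERMS = ("centroid_size", "sex", "temperature", "latitude")


@dataclass
class DeformationVector:
    term: str
    beta: np.ndarray
    model_formula: str
    n_units: int


@dataclass
class EbetaResult:
    e_beta: float
    ratio: float
    null_ratios: np.ndarray
    p: float
    n_perm: int
    seed: int | None


def _as_mat(d) -> np.ndarray:
    return d.matrix if isinstance(d, CovMatrix) else np.asarray(d, dtype=float)


def e_beta(d: CovMatrix | np.ndarray, beta: np.ndarray) -> float:
    """Variance of D along beta: ``beta' D beta / (beta' beta)``
    (a Rayleigh quotient, bounded by the extreme eigenvalues of D)."""
    mat = _as_mat(d)
    b = np.asarray(beta, dtype=float).ravel()
    if b.shape[0] != mat.shape[0]:
        raise ValueError("beta dimension does not match D")
    nrm = float(b @ b)
    if nrm <= 0:
        raise ValueError("beta must be a nonzero vector")
    return float(b @ mat @ b) / nrm


def e_beta_ratio(d: CovMatrix | np.ndarray, beta: np.ndarray) -> float:
    """Proportion of the total developmental variance (trace of D)
    captured along beta."""
    mat = _as_mat(d)
    tr = float(np.trace(mat))
    if tr <= 0:
        raise ValueError("D has zero trace")
    return e_beta(mat, beta) / tr


def randomization_test(d: CovMatrix | np.ndarray, beta: np.ndarray,
                       n_perm: int = 10000, seed: int | None = None,
                       null: str = "shuffle") -> EbetaResult:
    """Randomization test for alignment between D and beta (one-sided:
    large ``e_beta`` is the alternative).

    The default null reshuffles the entries of beta across the coordinate
    slots; ``null='sphere'`` instead draws uniform random directions.
    The p-value uses the (1 + exceedances)/(n_perm + 1) convention.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    mat = _as_mat(d)
    b = np.asarray(beta, dtype=float).ravel()
    observed = e_beta(mat, b)
    tr = float(np.trace(mat))
    rng = np.random.default_rng(seed)
    p_dim = b.shape[0]
    if null == "shuffle":
        if np.ptp(b) == 0:
            raise ValueError("all beta entries equal: shuffling gives a degenerate null")
        perms = np.argsort(rng.random((n_perm, p_dim)), axis=1)
        bmat = b[perms]
    elif null == "sphere":
        bmat = rng.standard_normal((n_perm, p_dim))
    else:
        raise ValueError(f"unknown null {null!r}")
    quad = np.einsum("ij,jk,ik->i", bmat, mat, bmat)
    norms = np.einsum("ij,ij->i", bmat, bmat)
    null_e = quad / norms
    p = (1.0 + float((null_e >= observed - 1e-15).sum())) / (n_perm + 1.0)
    return EbetaResult(
        e_beta=observed, ratio=observed / tr, null_ratios=null_e / tr,
        p=p, n_perm=n_perm, seed=seed,
    )


# --------------------------------------------------------------------------
# estimating deformation vectors


def _design_columns(df: pd.DataFrame, term: str) -> tuple[np.ndarray, list[str], int]:
    """Build the regression design and locate the column(s) of the term."""
    cols = [np.ones(len(df))]
    names = ["intercept"]
    cols.append(df["log_cs"].to_numpy(float))
    names.append("centroid_size")
    if term == "latitude":
        cols.append(df["latitude_deg"].to_numpy(float))
        names.append("latitude")
    else:
        if "sex" in df.columns and df["sex"].nunique() > 1:
            sexes = sorted(df["sex"].unique())
            cols.append(np.where(df["sex"] == sexes[-1], 1.0, -1.0))
            names.append("sex")
        if "population" in df.columns and df["population"].nunique() > 1:
            pops = sorted(df["population"].unique())
            for pop in pops[1:]:
                cols.append((df["population"] == pop).to_numpy(float))
                names.append(f"pop_{pop}")
        if "temperature_C" in df.columns and df["temperature_C"].nunique() > 1:
            temp = df["temperature_C"].to_numpy(float)
            cols.append(temp - temp.mean())
            names.append("temperature")
    x = np.column_stack(cols)
    if term not in names:
        raise ValueError(f"term {term!r} not identifiable in this design")
    return x, names, names.index(term)


def estimate_deformation_vector(data: AlignedDataset, term: str) -> DeformationVector:
    """Multivariate OLS estimate of a shape-deformation vector.

    For ``term='latitude'`` shapes are averaged by population and regressed
    on log centroid size and latitude; for allometry
    (``'centroid_size'``), ``'sex'`` and ``'temperature'`` shapes are
    averaged by isofemale line within sex and temperature cells and
    regressed on log centroid size, sex (coded -1/+1), population (fixed
    factor) and rearing temperature (linear, degrees C).
    """
    if term not in TERMS:
        raise ValueError(f"term must be one of {TERMS}")
    fac = data.factors.copy()
    fac["log_cs"] = data.log_centroid_size
    shape_cols = [f"c{i}" for i in range(data.shape_coords.shape[1])]
    table = pd.concat(
        [fac.reset_index(drop=True),
         pd.DataFrame(data.shape_coords, columns=shape_cols)], axis=1)

    if term == "latitude":
        if "population" not in table.columns or "latitude_deg" not in table.columns:
            raise ValueError("latitude vector needs population and latitude_deg factors")
        grouped = table.groupby("population", sort=False)
        mean_df = grouped[shape_cols + ["log_cs", "latitude_deg"]].mean().reset_index()
        formula = "Y ~ 1 + log_cs + latitude"
    else:
        if "line" not in table.columns:
            raise ValueError(f"{term} vector needs a 'line' factor column")
        keys = ["line"] + [c for c in ("sex", "temperature_C", "population") if c in table.columns]
        num = shape_cols + ["log_cs"]
        grouped = table.groupby(keys, sort=False)
        mean_df = grouped[num].mean().reset_index()
        formula = "Y ~ 1 + log_cs + sex + population + temperature"

    x, names, col = _design_columns(mean_df, term)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("collinear design: deformation vector not identifiable")
    y = mean_df[shape_cols].to_numpy()
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    beta = coef[col]
    if not np.all(np.isfinite(beta)):
        raise ValueError("non-finite regression coefficients")
    return DeformationVector(term=term, beta=beta, model_formula=formula,
                             n_units=len(mean_df))
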