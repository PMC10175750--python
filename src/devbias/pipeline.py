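"""Configuration-driven orchestration of the analysis stages.

A pipeline config (dict or YAML file) lists the analyses to run and their
parameters; every stochastic step takes an explicit seed.  Outputs are a
machine-readable JSON summary plus per-stage CSVs in the output directory.

Supported stages
----------------
``simulate``  : generate the synthetic study datasets (FA, lines, species)
``fa``        : GPA, allometry control, bilateral decomposition,
                Procrustes ANOVA, moment estimate of D
``matrices``  : factor-analytic REML fits (D, P and optionally G/R)
``compare``   : common-subspace comparison of two matrix CSVs along a
                reference matrix
``ebeta``     : projection of D onto a deformation vector + randomization
``disparity`` : Procrustes variance of two groups + permutation test
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import yaml

from .align import gpa_align, residualize_allometry
from .covmatrix import CovMatrix
from .deformation import randomization_test
from .disparity import disparity_test
from .io import write_long_csv, write_tps
from .models import fit_factor_analytic
from .reml import reml_mvn_resample
from .simulate import default_spec, simulate_fa_dataset, simulate_line_dataset
from .subspace import compare_matrices, eigenbasis, subspace_ci
from .symmetry import bilateral_decompose, estimate_D, procrustes_anova

log = logging.getLogger("devbias")


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError("pipeline config must be a mapping")
    return config


def run_pipeline(config, outdir: str | Path | None = None) -> dict:
    """Execute the requested stages in dependency order; returns (and
    writes) a JSON-serialisable report."""
    cfg = _load_config(config)
    outdir = Path(outdir or cfg.get("output_dir", "devbias_output"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    analyses = cfg.get("analyses", ["simulate", "fa"])
    import devbias
    report: dict = {"version": devbias.__version__, "seed": seed, "stages": {}}

    spec = None
    fa_data = None
    d_moment = None
    reference = None
    if cfg.get("reference"):
        from .io import read_landmarks
        reference = read_landmarks(cfg["reference"], cfg.get("reference_format", "tps")) \
            .observations[0].coords

    if "simulate" in analyses:
        spec = default_spec(seed=seed, **cfg.get("simulate", {}).get("overrides", {}))
        if reference is None:
            reference = spec.mean_shape
        fa_data = simulate_fa_dataset(spec)
        write_tps(fa_data, outdir / "fa_dataset.tps")
        report["stages"]["simulate"] = {
            "n_fa_observations": len(fa_data),
            "seed": seed,
        }
        if cfg.get("simulate", {}).get("lines", False):
            line_data = simulate_line_dataset(spec)
            write_long_csv(line_data, outdir / "line_dataset.csv",
                           meta={"generator": "devbias.simulate"})
            report["stages"]["simulate"]["n_line_observations"] = len(line_data)

    if "fa" in analyses:
        if fa_data is None:
            from .io import read_landmarks
            fa_cfg = cfg.get("fa", {})
            fa_data = read_landmarks(fa_cfg["input"], fa_cfg.get("format", "tps"),
                                     factors=fa_cfg.get("factors"))
        aligned = gpa_align(fa_data, reference=reference, reflect_sides=True)
        aligned = residualize_allometry(aligned)
        comps = bilateral_decompose(aligned)
        table = procrustes_anova(comps)
        table.to_csv(outdir / "procrustes_anova.csv")
        d_moment = estimate_D(comps)
        d_moment.to_csv(outdir / "D_moment.csv")
        report["stages"]["fa"] = {
            "n_individuals": comps.n_individuals,
            "F_individual_x_side": float(table.loc["individual_x_side", "F"]),
            "eta2_individual_x_side": float(table.loc["individual_x_side", "eta_squared"]),
            "trace_D": d_moment.trace,
            "antisymmetry_excess_kurtosis": comps.antisymmetry_excess_kurtosis,
        }

    if "matrices" in analyses:
        m_cfg = cfg.get("matrices", {})
        rank = int(m_cfg.get("rank", 5))
        aligned = gpa_align(fa_data, reference=reference, reflect_sides=True)
        aligned = residualize_allometry(aligned)
        fits = {}
        for design in m_cfg.get("designs", ["D", "P"]):
            fit = fit_factor_analytic(aligned, design, rank_q=rank,
                                      seed=seed, n_restarts=int(m_cfg.get("restarts", 3)))
            fits[design] = fit
            fit.cov_matrix().to_csv(outdir / f"{design}_reml.csv")
        report["stages"]["matrices"] = {
            d: {"trace": f.cov_matrix().trace, "aic": f.aic,
                "converged": f.converged, "rank_q": f.rank_q}
            for d, f in fits.items()
        }
        if "compare" in analyses and "compare" not in cfg:
            ref = fits.get("P", next(iter(fits.values())))
            basis = eigenbasis(ref.cov_matrix())
            k = min(int(m_cfg.get("k", rank)), basis.p)
            x_fit = fits.get("P", next(iter(fits.values())))
            d_fit = fits.get("D", next(iter(fits.values())))
            res = compare_matrices(x_fit.cov_matrix(), d_fit.cov_matrix(), basis, k)
            n_draws = int(m_cfg.get("n_draws", 0))
            if n_draws:
                xd = [c.matrix for c in reml_mvn_resample(x_fit, n_draws, seed + 11)]
                dd = [c.matrix for c in reml_mvn_resample(d_fit, n_draws, seed + 12)]
                res = subspace_ci(xd, dd, basis, k, seed=seed + 13, point=res)
            report["stages"]["compare"] = _subspace_report(res)

    if "compare" in analyses and "compare" in cfg:
        c_cfg = cfg["compare"]
        x = CovMatrix.from_csv(c_cfg["x"], validate=False)
        d = CovMatrix.from_csv(c_cfg["d"], validate=False)
        ref = CovMatrix.from_csv(c_cfg["reference"], validate=False)
        basis = eigenbasis(ref)
        k = int(c_cfg.get("k", min(x.rank, d.rank)))
        res = compare_matrices(x, d, basis, k)
        report["stages"]["compare"] = _subspace_report(res)

    if "ebeta" in analyses:
        e_cfg = cfg.get("ebeta", {})
        if "d" in e_cfg:
            d = CovMatrix.from_csv(e_cfg["d"], validate=False)
        elif d_moment is not None:
            d = d_moment
        else:
            raise ValueError("ebeta stage needs a D matrix")
        beta = np.loadtxt(e_cfg["beta"], delimiter=",") if "beta" in e_cfg \
            else np.linalg.eigh(d.matrix)[1][:, -1]
        result = randomization_test(d, beta, n_perm=int(e_cfg.get("n_perm", 10000)),
                                    seed=seed + 21)
        np.savetxt(outdir / "ebeta_null.csv", result.null_ratios, delimiter=",",
                   header="null_ratio")
        report["stages"]["ebeta"] = {
            "e_beta": result.e_beta, "ratio": result.ratio, "p": result.p,
            "null_mean_ratio": float(result.null_ratios.mean()),
            "n_perm": result.n_perm,
        }

    if "disparity" in analyses:
        d_cfg = cfg.get("disparity", {})
        if "group_a" in d_cfg:
            a = np.loadtxt(d_cfg["group_a"], delimiter=",", ndmin=2)
            b = np.loadtxt(d_cfg["group_b"], delimiter=",", ndmin=2)
            res = disparity_test(a, b, n_perm=int(d_cfg.get("n_perm", 1000)),
                                 seed=seed + 31)
            report["stages"]["disparity"] = {
                "variance_a": res.variance_a, "variance_b": res.variance_b,
                "abs_difference": res.abs_difference, "z": res.z, "p": res.p,
            }

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    log.info("pipeline complete: %s", outdir / "report.json")
    return report


def _subspace_report(res) -> dict:
    out = {"r2": res.r2, "b": res.slope_b, "intercept": res.intercept,
           "k": res.k, "dropped_dims": list(res.dropped_dims)}
    if res.ci_r2 is not None:
        out["ci_r2"] = list(res.ci_r2)
        out["ci_b"] = list(res.ci_slope)
        out["n_resamples"] = res.n_resamples
        out["dropped_draws"] = res.dropped_draw_count
    return out
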