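"""Synthetic landmark data with the exact structure the analysis assumes.

Every generator draws from the hierarchical Gaussian model underlying the
estimators: a mean wing shape perturbed by multivariate-normal deviations
at each design level (allometry along log centroid size, among-individual
covariance, a fixed directional-asymmetry offset, per-side FA deviations
with covariance D, among-line covariance G, measurement error E) and, for
interspecific data, species means evolving by Brownian motion with rate
matrix R on a cladogram.  Deviation covariances are supported on the
18-dimensional shape subspace (translation, scale and rotation directions
projected out at the mean shape), so Procrustes alignment of the emitted
raw coordinates recovers the generating structure.

Datasets are emitted as RAW coordinates: each observation receives a
random rotation, translation and its centroid size, and left wings are
mirrored, so the full superimposition pipeline is exercised.

Default parameter values emulate the study conditions: 87 individuals x 2
sides x 2 replicates for the FA design; 74 isofemale lines in 7
populations reared at five temperatures in both sexes for the genetic
design; 36 species on a random cladogram with Grafen branch lengths for
the divergence design.  Trait scales (trace of D ~ 1.15e-4, etc.) follow
the same study.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .align import _center_and_scale, _nuisance_basis
from .covmatrix import CovMatrix
from .data import LandmarkConfiguration, ShapeDataset
from .phylo import grafen_branch_lengths, random_cladogram

#: 11 wing-like landmarks (vein intersections and terminations along a
#: generic dipteran wing outline), centered, unit centroid size
DEFAULT_MEAN_SHAPE = np.array([
    [0.00, 0.00],    # wing base
    [0.18, 0.08],
    [0.35, 0.12],
    [0.62, 0.10],
    [0.95, 0.02],    # distal tip
    [0.80, -0.06],
    [0.55, -0.11],
    [0.28, -0.10],
    [0.45, 0.02],    # anterior crossvein
    [0.60, -0.03],   # posterior crossvein
    [0.12, -0.05],
])
DEFAULT_MEAN_SHAPE, _ = _center_and_scale(DEFAULT_MEAN_SHAPE)


def shape_space_projector(mean_shape: np.ndarray) -> np.ndarray:
    """Projector onto the shape subspace at ``mean_shape`` (removes the two
    translation directions plus the scale and rotation directions)."""
    k = mean_shape.shape[0]
    flat, _ = _center_and_scale(mean_shape)
    flat = flat.ravel()
    tx = np.tile([1.0, 0.0], k) / np.sqrt(k)
    ty = np.tile([0.0, 1.0], k) / np.sqrt(k)
    basis = [tx, ty, *(_nuisance_basis(flat))]
    b = np.stack(basis)
    # orthonormalize (translation is already orthogonal to scale/rotation
    # because the mean shape is centered)
    q, _ = np.linalg.qr(b.T)
    return np.eye(2 * k) - q @ q.T


def make_low_rank_cov(p: int, rank: int, eigenvalue_decay: float = 0.5,
                      seed: int | None = None, trace: float = 1.0) -> CovMatrix:
    """Random covariance with ``rank`` nonzero eigenvalues decaying
    geometrically (``lambda_i ~ decay**i``), rotated by a random
    orthonormal basis and scaled to the requested trace."""
    if not 1 <= rank <= p:
        raise ValueError("rank must satisfy 1 <= rank <= p")
    if eigenvalue_decay <= 0:
        raise ValueError("eigenvalue_decay must be positive")
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((p, p)))
    lam = np.zeros(p)
    lam[:rank] = eigenvalue_decay ** np.arange(rank)
    lam *= trace / lam.sum()
    mat = (q * lam) @ q.T
    return CovMatrix((mat + mat.T) / 2.0, label="D", source="synthetic low-rank",
                     validate=False)


def project_to_shape_space(cov: CovMatrix | np.ndarray, mean_shape: np.ndarray,
                           keep_trace: bool = True) -> np.ndarray:
    """Restrict a covariance matrix to the shape subspace at the mean."""
    mat = cov.matrix if isinstance(cov, CovMatrix) else np.asarray(cov, float)
    proj = shape_space_projector(mean_shape)
    out = proj @ mat @ proj
    out = (out + out.T) / 2.0
    if keep_trace and np.trace(out) > 0:
        out *= np.trace(mat) / np.trace(out)
    return out


def _shape_cov(p: int, rank: int, decay: float, seed: int, trace: float,
               mean_shape: np.ndarray) -> np.ndarray:
    raw = make_low_rank_cov(p, rank, decay, seed, trace).matrix
    return project_to_shape_space(raw, mean_shape)


def common_shape_basis(mean_shape: np.ndarray, seed: int) -> np.ndarray:
    """A random orthonormal basis of the shape subspace (p x (p - 4)
    columns): the common principal axes shared by the generating
    covariance matrices."""
    proj = shape_space_projector(mean_shape)
    w, v = np.linalg.eigh(proj)
    span = v[:, w > 0.5]                      # eigenvalue 1 subspace
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((span.shape[1], span.shape[1])))
    return span @ q


def related_spectrum(base_log: np.ndarray, rank: int, slope: float,
                     r2: float, seed: int) -> np.ndarray:
    """Eigenvalues log-linearly related to a base spectrum.

    ``log lambda_i = slope * base_log_i + eps_i`` with the noise variance
    chosen so the squared correlation between the two log spectra equals
    ``r2`` (the common-subspace coefficient of determination when both
    matrices share eigenvectors).  ``base_log`` is extrapolated linearly
    beyond its length when ``rank`` exceeds it.
    """
    if not 0 < r2 <= 1:
        raise ValueError("r2 must be in (0, 1]")
    step = base_log[1] - base_log[0] if len(base_log) > 1 else -0.5
    ext = np.concatenate([base_log,
                          base_log[-1] + step * np.arange(1, rank - len(base_log) + 1)]) \
        if rank > len(base_log) else base_log[:rank]
    var_base = float(np.var(ext))
    sd_eps = np.sqrt(slope ** 2 * var_base * (1.0 / r2 - 1.0))
    rng = np.random.default_rng(seed)
    return np.exp(slope * ext + sd_eps * rng.standard_normal(rank))


def _basis_cov(basis: np.ndarray, lam: np.ndarray, trace: float) -> np.ndarray:
    """Covariance with the given eigenvalues on the leading common-basis
    axes, scaled to the requested trace."""
    lam = np.asarray(lam, float) * (trace / lam.sum())
    vecs = basis[:, : len(lam)]
    mat = (vecs * lam) @ vecs.T
    return (mat + mat.T) / 2.0


def _structured_vector(cov: np.ndarray, align_frac: float, norm: float,
                       seed: int) -> np.ndarray:
    """A vector of given norm partially aligned with the leading
    eigenvector of ``cov`` (the rest random within the same space)."""
    w, v = np.linalg.eigh(cov)
    lead = v[:, -1]
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(cov.shape[0])
    span = v[:, w > 1e-12 * w[-1]]
    noise = span @ (span.T @ noise)
    noise -= (noise @ lead) * lead
    noise /= max(np.linalg.norm(noise), 1e-12)
    vec = align_frac * lead + np.sqrt(max(1 - align_frac ** 2, 0.0)) * noise
    return norm * vec / np.linalg.norm(vec)


@dataclass
class SyntheticSpec:
    """Ground-truth parameters and design sizes for the generators."""

    mean_shape: np.ndarray
    D_true: np.ndarray
    P_ind_true: np.ndarray
    G_true: np.ndarray
    E_true: np.ndarray
    R_true: np.ndarray
    pop_true: np.ndarray
    directional_asym: np.ndarray
    allometry_vector: np.ndarray
    sex_vector: np.ndarray
    temperature_vector: np.ndarray
    latitude_vector: np.ndarray
    D2_true: np.ndarray | None = None      # second (reference) species
    P2_ind_true: np.ndarray | None = None
    G2_true: np.ndarray | None = None
    n_individuals2: int = 96
    log_cs_mean: float = np.log(2.0)
    log_cs_sd: float = 0.06
    n_individuals: int = 87
    n_replicates: int = 2
    lines_per_population: tuple[int, ...] = (11, 11, 11, 11, 11, 10, 9)
    population_latitudes: tuple[float, ...] = (37.0, 41.0, 45.0, 49.0, 53.0, 57.0, 61.0)
    temperatures: tuple[float, ...] = (15.0, 18.0, 23.0, 28.0, 31.0)
    lines_per_population2: tuple[int, ...] = (5, 5, 5, 5, 5, 5, 4, 4, 4)
    population_latitudes2: tuple[float, ...] = (38.0, 41.0, 44.0, 47.0, 50.0, 53.0, 56.0, 59.0, 62.0)
    temperatures2: tuple[float, ...] = (12.0, 18.0, 24.0, 30.0)
    sexes: tuple[str, ...] = ("f", "m")
    n_per_cell: int = 2
    n_species: int = 36
    n_per_species: int = 5
    tree: dendropy.Tree | str | None = None
    translation_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        p = 2 * self.mean_shape.shape[0]
        for name in ("D_true", "P_ind_true", "G_true", "E_true", "R_true",
                     "pop_true", "D2_true", "P2_ind_true", "G2_true"):
            if getattr(self, name) is None:
                continue
            mat = np.asarray(getattr(self, name), float)
            if mat.shape != (p, p):
                raise ValueError(f"{name} must be {p}x{p}")
            w = np.linalg.eigvalsh(mat)
            if w[0] < -1e-8 * max(w[-1], 1e-300):
                raise ValueError(f"{name} is not PSD")
            setattr(self, name, mat)
        if self.n_individuals < 2 or self.n_replicates < 1:
            raise ValueError("need >= 2 individuals and >= 1 replicate")
        if len(self.lines_per_population) != len(self.population_latitudes):
            raise ValueError("one latitude per population required")
        if len(self.lines_per_population2) != len(self.population_latitudes2):
            raise ValueError("one latitude per population required (species B)")

    @property
    def p(self) -> int:
        return 2 * self.mean_shape.shape[0]


def default_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """Study-condition defaults; ``overrides`` replace individual fields.

    The generating covariance matrices share a common set of principal
    axes (the study system's central empirical feature: developmental
    bias predicts phenotypic, genetic and macroevolutionary covariation)
    with log-spectra related to D's by the study's printed slopes and
    coefficients of determination (D-D across species b=0.65 r2=0.90;
    P b=1.10 r2=0.83; G b=1.27 r2=0.83; second-species G b=1.03 r2=0.81;
    R b=1.27 r2=0.77).  Trait scales also follow the study: trace of D
    ~1.15e-4 (second species 0.93e-4); measurement error sized so the FA
    interaction F is ~27 at two replicates; among-individual variance
    sized so FA is ~8% of total shape variation; the BM rate trace
    matches the observed interspecific disparity scale.  Deformation
    vectors are aligned with D's leading axis at fractions chosen to
    reproduce the printed e_beta ratios (allometry 24%, sex 15%,
    temperature 9%, latitude 14% of tr(D)).
    """
    mean = DEFAULT_MEAN_SHAPE
    p = mean.size
    basis = common_shape_basis(mean, seed + 100)
    log_d = np.log(0.70) * np.arange(9)          # D spectrum, rank 9
    lam_d = np.exp(log_d)
    d = _basis_cov(basis, lam_d, 11.5e-5)
    d2 = _basis_cov(basis, related_spectrum(log_d, 9, 0.65, 0.90, seed + 101), 9.3e-5)
    p_ind = _basis_cov(basis, related_spectrum(log_d, 12, 1.10, 0.83, seed + 102), 6.2e-4)
    p2_ind = _basis_cov(basis, np.sort(related_spectrum(log_d, 12, 1.10, 0.83, seed + 103))[::-1], 6.2e-4)
    g = _basis_cov(basis, related_spectrum(log_d, 9, 1.27, 0.83, seed + 104), 3.0e-4)
    g2 = _basis_cov(basis, related_spectrum(log_d, 9, 1.03, 0.81, seed + 105), 2.5e-4)
    r = _basis_cov(basis, related_spectrum(log_d, 12, 1.27, 0.77, seed + 106), 5.88e-3)
    pop = _shape_cov(p, rank=4, decay=0.6, seed=seed + 107, trace=5.0e-5, mean_shape=mean)
    proj = shape_space_projector(mean)
    rng = np.random.default_rng(seed + 108)
    da = proj @ rng.standard_normal(p)
    da *= 0.01 / np.linalg.norm(da)
    fields = dict(
        mean_shape=mean, D_true=d, P_ind_true=p_ind, G_true=g,
        E_true=project_to_shape_space(np.eye(p) * 8.8e-6 / p, mean),
        R_true=r, pop_true=pop,
        D2_true=d2, P2_ind_true=p2_ind, G2_true=g2,
        directional_asym=da,
        allometry_vector=_structured_vector(d, 0.68, 0.02, seed + 109),
        sex_vector=_structured_vector(d, 0.49, 0.01, seed + 110),
        temperature_vector=_structured_vector(d, 0.30, 5e-4, seed + 111),
        latitude_vector=_structured_vector(d, 0.46, 5e-4, seed + 112),
        seed=seed,
    )
    fields.update(overrides)
    return SyntheticSpec(**fields)


# --------------------------------------------------------------------------
# raw-coordinate embedding


def _mvn_factor(cov: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(cov)
    return v * np.sqrt(np.clip(w, 0.0, None))


def _embed_raw(shape_vec: np.ndarray, size: float, side: str,
               rng: np.random.Generator, translation_sd: float) -> np.ndarray:
    config = shape_vec.reshape(-1, 2) * size
    if side == "left":
        config = config * np.array([-1.0, 1.0])
    theta = rng.uniform(0.0, 2.0 * np.pi)
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    return config @ rot.T + rng.normal(0.0, translation_sd, size=2)


# --------------------------------------------------------------------------
# generators


def simulate_fa_dataset(spec: SyntheticSpec, species: str = "A") -> ShapeDataset:
    """FA design: individuals x {left, right} x replicate measurements.

    Per-side FA deviations are drawn independently with covariance
    ``D_true`` (the one-side-contribution convention), so the REML and
    moment estimators of D target ``D_true`` exactly.  ``species='B'``
    uses the second species' matrices and sample size.
    """
    if species == "A":
        d_true, p_true, n_ind = spec.D_true, spec.P_ind_true, spec.n_individuals
        rng = np.random.default_rng(spec.seed)
    elif species == "B":
        if spec.D2_true is None or spec.P2_ind_true is None:
            raise ValueError("spec has no second-species matrices")
        d_true, p_true, n_ind = spec.D2_true, spec.P2_ind_true, spec.n_individuals2
        rng = np.random.default_rng(spec.seed + 7000)
    else:
        raise ValueError("species must be 'A' or 'B'")
    f_ind = _mvn_factor(p_true)
    f_d = _mvn_factor(d_true)
    f_e = _mvn_factor(spec.E_true)
    mean_flat = spec.mean_shape.ravel()
    observations, rows = [], []
    for i in range(n_ind):
        ident = f"ind_{i + 1:03d}"
        log_cs = rng.normal(spec.log_cs_mean, spec.log_cs_sd)
        base = (mean_flat
                + spec.allometry_vector * (log_cs - spec.log_cs_mean)
                + f_ind @ rng.standard_normal(spec.p))
        for side, sign in (("left", -1.0), ("right", 1.0)):
            cell = base + sign * spec.directional_asym / 2.0 \
                + f_d @ rng.standard_normal(spec.p)
            for rep in range(1, spec.n_replicates + 1):
                vec = cell + f_e @ rng.standard_normal(spec.p)
                coords = _embed_raw(vec, np.exp(log_cs), side, rng,
                                    spec.translation_sd)
                observations.append(LandmarkConfiguration(ident, side, rep, coords))
                rows.append({"individual": ident, "side": side, "measurement": rep})
    return ShapeDataset(observations, pd.DataFrame(rows))


def simulate_line_dataset(spec: SyntheticSpec, species: str = "A") -> ShapeDataset:
    """Common-garden design: isofemale lines within populations, reared at
    several temperatures in both sexes.

    Population effects combine a latitudinal shape trend with random
    population noise; line effects have covariance ``G_true``; individual
    residuals have covariance ``P_ind_true + E_true``.  ``species='B'``
    uses the second species' G matrix and rearing design.
    """
    if species == "A":
        g_true, p_true = spec.G_true, spec.P_ind_true
        lines_per_pop = spec.lines_per_population
        latitudes, temperatures = spec.population_latitudes, spec.temperatures
        rng = np.random.default_rng(spec.seed + 1)
    elif species == "B":
        if spec.G2_true is None or spec.P2_ind_true is None:
            raise ValueError("spec has no second-species matrices")
        g_true, p_true = spec.G2_true, spec.P2_ind_true
        lines_per_pop = spec.lines_per_population2
        latitudes, temperatures = spec.population_latitudes2, spec.temperatures2
        rng = np.random.default_rng(spec.seed + 8000)
    else:
        raise ValueError("species must be 'A' or 'B'")
    f_g = _mvn_factor(g_true)
    f_pop = _mvn_factor(spec.pop_true)
    f_res = _mvn_factor(p_true + spec.E_true)
    mean_flat = spec.mean_shape.ravel()
    temps = np.asarray(temperatures)
    t_center = temps.mean()
    lat = np.asarray(latitudes)
    lat_center = lat.mean()
    observations, rows = [], []
    line_no = 0
    for p_i, n_lines in enumerate(lines_per_pop):
        pop_name = f"pop_{p_i + 1}"
        pop_eff = (spec.latitude_vector * (lat[p_i] - lat_center)
                   + f_pop @ rng.standard_normal(spec.p))
        for _ in range(n_lines):
            line_no += 1
            line_name = f"line_{line_no:03d}"
            line_eff = f_g @ rng.standard_normal(spec.p)
            for sex in spec.sexes:
                sex_sign = 1.0 if sex == spec.sexes[-1] else -1.0
                for temp in temps:
                    for k in range(spec.n_per_cell):
                        log_cs = rng.normal(
                            spec.log_cs_mean - 0.004 * (temp - t_center),
                            spec.log_cs_sd)
                        vec = (mean_flat + pop_eff + line_eff
                               + sex_sign * spec.sex_vector
                               + spec.temperature_vector * (temp - t_center)
                               + spec.allometry_vector * (log_cs - spec.log_cs_mean)
                               + f_res @ rng.standard_normal(spec.p))
                        ident = f"{line_name}_{sex}_{temp:g}_{k + 1}"
                        coords = _embed_raw(vec, np.exp(log_cs), "right", rng,
                                            spec.translation_sd)
                        observations.append(
                            LandmarkConfiguration(ident, "right", 1, coords))
                        rows.append({
                            "individual": ident, "side": "right", "measurement": 1,
                            "line": line_name, "population": pop_name,
                            "sex": sex, "temperature_C": float(temp),
                            "latitude_deg": float(lat[p_i]),
                        })
    return ShapeDataset(observations, pd.DataFrame(rows))


def simulate_species_means(tree: "dendropy.Tree | str", r_true: np.ndarray,
                           seed: int | None = None,
                           root: np.ndarray | None = None) -> pd.DataFrame:
    """Multivariate Brownian motion on a tree: one mean shape row per tip.

    Increments along each branch are N(0, branch_length * R); missing
    branch lengths are an error (apply a branch-length rule first).
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    else:
        tree = tree.clone(depth=1)
    r_true = np.asarray(r_true, float)
    p = r_true.shape[0]
    factor = _mvn_factor(r_true)
    rng = np.random.default_rng(seed)
    root_val = np.zeros(p) if root is None else np.asarray(root, float).ravel()
    values: dict[int, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = root_val
            continue
        bl = node.edge.length
        if bl is None:
            raise ValueError("tree has missing branch lengths")
        step = factor @ rng.standard_normal(p) * np.sqrt(max(bl, 0.0))
        values[id(node)] = values[id(node.parent_node)] + step
    rows = {}
    for i, leaf in enumerate(tree.leaf_node_iter()):
        label = leaf.taxon.label if leaf.taxon else f"tip_{i}"
        rows[label] = values[id(leaf)]
    return pd.DataFrame.from_dict(rows, orient="index")


def simulate_species_dataset(spec: SyntheticSpec
                             ) -> tuple[ShapeDataset, dendropy.Tree]:
    """Interspecific design: Brownian species means on a Grafen-scaled
    cladogram plus within-species individual variation."""
    tree = spec.tree
    if tree is None:
        tree = random_cladogram(spec.n_species, seed=spec.seed + 2)
    tree = grafen_branch_lengths(tree)
    means = simulate_species_means(tree, spec.R_true, seed=spec.seed + 3,
                                   root=spec.mean_shape.ravel())
    rng = np.random.default_rng(spec.seed + 4)
    f_res = _mvn_factor(spec.P_ind_true + spec.E_true)
    observations, rows = [], []
    for species, mean_vec in means.iterrows():
        base = mean_vec.to_numpy()
        for k in range(spec.n_per_species):
            vec = base + f_res @ rng.standard_normal(spec.p)
            log_cs = rng.normal(spec.log_cs_mean, spec.log_cs_sd)
            ident = f"{species}_{k + 1}"
            coords = _embed_raw(vec, np.exp(log_cs), "right", rng,
                                spec.translation_sd)
            observations.append(LandmarkConfiguration(ident, "right", 1, coords))
            rows.append({"individual": ident, "side": "right",
                         "measurement": 1, "species": str(species)})
    return ShapeDataset(observations, pd.DataFrame(rows)), tree
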