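# Methods

## Shape variables

Each wing is 11 two-dimensional landmarks. Generalized Procrustes analysis
centers every configuration, scales it to unit centroid size (CS; recorded
before scaling, with ln CS used for allometry), and rotates it by the
closed-form 2-D least-squares rotation either onto a supplied reference
configuration or onto an iteratively re-estimated consensus. Aligned
configurations are projected orthogonally onto the tangent space at the
consensus, leaving 22 coordinates of which 18 carry shape information
(two translation directions, the scale direction and the infinitesimal
rotation direction are removed to below 1e-10 of total variance).

Two conventions matter downstream:

* **Matching symmetry.** Left wings are mirrored by negating x before
  joint alignment; landmark correspondence is preserved.
* **Frame.** Without a reference, the consensus is put in a canonical
  orientation (major principal axis along x, the landmark furthest from
  the centroid pointing to +x), which makes alignment exactly invariant
  to similarity transforms of the input. Covariance matrices estimated
  from *different* datasets are only comparable when all datasets were
  aligned to one common reference configuration, because a rotation of
  the digitizing frame acts as an orthogonal transformation of the 22
  coordinates. Every cross-dataset analysis here therefore aligns to a
  single reference (for synthetic data, the generating mean shape).

Allometry is removed, where stated, by multivariate OLS of the 22 shape
coordinates on ln CS; residuals are mean-centered and the 22-vector of
slopes is retained (it is also the allometric deformation vector).

## Asymmetry decomposition and D

For individuals i, sides s ∈ {L, R} and replicate measurements r, the
aligned coordinates decompose by least squares into grand mean,
individual effects (the symmetric component), a side effect (directional
asymmetry, DA = mean right − left), the individual × side interaction
(fluctuating asymmetry, FA) and replicate error. The per-individual FA
deviation stored is the half signed contrast adjusted for DA,
f_i = ((ȳ_iR − ȳ_iL) − DA)/2.

The developmental matrix **D** is defined as the covariance of *one
side's* FA effect: in the mixed-model formulation y = individual + side +
u_{is} + e with u_{is} iid N(0, D), D is the covariance of u. Two
estimators target exactly this quantity and agree closely in practice:

* moment: D̂ = (MS_int − MS_err)/m with MS_int = 2m Σ f_i f_iᵀ/(n−1),
  m = replicates per cell (tiny negative eigenvalues produced by the
  error subtraction are clipped to zero by default);
* REML with the factor-analytic model below (fixed individual and side,
  random individual × side).

Note the raw covariance of the stored half-contrasts estimates
D/2 + E/(2m), not D; the correction above is what makes the estimator
unbiased for the per-side convention.

The Procrustes ANOVA sums squared deviations over all 22 coordinates and
uses the univariate design degrees of freedom: individual (n−1), side
(1), individual × side ((n−1)(s−1)), error (ns(m−1)). FA is tested
against the replicate error; main effects against the interaction. η² is
SS_effect/SS_total. With a single replicate the error stratum is empty
and the FA p-value is reported as unavailable. Antisymmetry is screened
by the excess kurtosis of the signed asymmetry projected on its first
principal axis (clearly negative values would indicate bimodality); the
diagnostic is reported, never used as a gate.

## Factor-analytic REML

All covariance matrices (D, P, G, R) are estimated as reduced-rank
factor-analytic REML fits: the random-effect covariance is
Σ_u = ΛΛᵀ + diag(ψ) with q factor columns (p·q − q(q−1)/2 free loadings
after zeroing the strict upper triangle of the first q rows, plus p
specific variances), and the residual covariance is diagonal with a
separate error variance per shape variable. Coordinates are multiplied by
10,000 before fitting (pure conditioning; results are rescaled), and
variances are log-parameterised.

For the balanced designs used here the restricted likelihood factorises
into independent strata (scatter matrix S_k, degrees of freedom df_k,
covariance V_k linear in the components):

* D design: interaction stratum V = Σ_e + mΣ_u, error stratum V = Σ_e;
* P design (fixed side, random individual): between-individual stratum
  V = Σ_e + smΣ_u, residual stratum;
* G design (fixed sex and rearing temperature as factors, random
  isofemale line): between-line-within-population stratum
  V = Σ_e + mΣ_u, residual stratum. Population enters as an additional
  random component only when line counts per population are equal;
  otherwise it is absorbed as a fixed effect, which keeps the strata
  factorisation exact and leaves the line-level matrix unaffected in
  expectation.

−2ℓ_R = Σ_k [df_k ln|V_k| + tr(V_k⁻¹S_k)] is minimised by L-BFGS-B with
analytic gradients and up to five jittered restarts from moment-based
starting values. Convergence is declared when the optimiser reports
success or the final gradient is negligible (|g|_max < 1; loading
rotations are weakly identified near the optimum, so the iteration
budget can be exhausted at a stationary point). On balanced one-way data
the fit reproduces the closed-form ANOVA estimator (MSB − MSW)/r to
1e-6 and matches lme4.

**Phylogenetic model (R).** Species effects have covariance S ⊗ Σ_u with
S the relationship matrix (S_ij = root-to-MRCA path length; under
Grafen's rule node height = (descendant tips − 1)/(total tips − 1), so
the diagonal is 1). Rotating species means into the eigenbasis of S
yields independent blocks V_i = δ_iΣ_u + Σ_e/m; the grand mean is
profiled by GLS with the usual REML log-determinant correction, and
because Σ_e is diagonal all blocks share one p × p eigenbasis per
evaluation. The gradient uses the REML identity
tr(P dV) − yᵀP dV P y evaluated in that basis (verified against central
differences at 1e-9). Equal within-species replication is required.

**Rank selection.** Fits proceed q = 1, 2, … until the AIC
(−2ℓ_R + 2 × number of variance parameters; REML-AIC counts no fixed
effects) improves by less than 2 or a fit fails to converge; the chosen
rank is the smallest within 2 of the minimum among converged fits.

**REML-MVN resampling.** The sampling covariance of vech(Σ_u) is
obtained by the delta method from the inverse observed information
(finite differences of the analytic gradient) and matrices are drawn
directly on the variance scale ("G-scale") from a multivariate normal
centered at the estimate. Draws that are not positive semidefinite are
retained but flagged — with a reduced-rank point estimate most draws
perturb the null space into indefiniteness, and dropping them would bias
the intervals; dimensions with nonpositive projected variances are
dropped per draw and counted instead.

## Common-subspace comparison

The reference matrix (a second species' P throughout, so that neither
compared matrix supplies its own basis) is decomposed into eigenvectors
K ordered by descending eigenvalue, each vector's largest-magnitude
entry made positive (signs do not affect quadratic forms; exact
eigenvalue ties leave the basis arbitrary within the tied subspace).
The variance of X along k_i is k_iᵀXk_i; complete projection conserves
tr(X). For a pair (X, D), natural-log variances over the first
k = min(rank_X, rank_D) supported dimensions are compared by OLS with
**D as predictor and X as response**; r² and the slope b are reported.
Dimensions with nonpositive projected variance are dropped and recorded;
fewer than three usable dimensions is an error. Percentile 95% intervals
for r² and b are computed from REML-MVN draws, paired by index when the
draw lists have equal length and cross-paired at random otherwise.

## Deformation vectors and e_β

Shape deformation vectors are partial-coefficient rows of multivariate
OLS fits: for latitude, population-mean shape on ln CS and latitude; for
allometry, sex and temperature, line-averaged shape (within sex ×
temperature cells) on ln CS, sex (coded −1/+1), population (fixed
factor) and temperature (linear, °C). The developmental variance along a
vector is the Rayleigh quotient e_β = βᵀDβ/βᵀβ (bounded by the extreme
eigenvalues of D and invariant to the scale of β), reported as
e_β/tr(D). The one-sided randomization test reshuffles the 22 entries of
β across coordinate slots (preserving length and entry distribution;
a uniform-directions null is available behind a flag) and uses the
(1 + exceedances)/(n_perm + 1) p-value convention, as do all permutation
tests in the package. The permutation null is exchangeability of β's
entries; an estimated β whose sampling noise is strongly structured
(e.g. by a shared residual covariance) can violate that null even when
the true effect is zero, which is a property of the test itself, not of
this implementation.

## Disparity

Procrustes variance of a set of aligned shapes is the mean squared
distance to their mean (trace of the divisor-n covariance). Clade
differences are tested by permuting clade labels (vectorised over
permutations), with Z = (observed − null mean)/null SD.

## Synthetic data

The generator draws from exactly the hierarchical Gaussian model the
estimators assume: mean shape plus allometry × ln CS (log-normal CS),
among-individual deviations ~ N(0, P_ind), a fixed DA offset split ± half
per side, per-side FA deviations ~ N(0, D) — the one-side convention, so
the estimators above target the generating D exactly — and replicate
error ~ N(0, E); line effects ~ N(0, G) under the common-garden design;
species means by multivariate Brownian motion (increments
N(0, branch length × R)) on a Grafen-scaled random cladogram. All
generating covariances live in the 18-dimensional shape subspace, and
every observation is emitted as raw coordinates with a random rotation,
translation and its centroid size (left wings mirrored), so
superimposition is always exercised.

Default parameters are the study conditions: 87 (species A) and 96
(species B) males × 2 sides × 2 replicate measurements; 74 isofemale
lines over 7 populations (latitudes 37–61°) at temperatures
{15, 18, 23, 28, 31} °C in both sexes, with unequal line counts per
population as in the field design (a 42-line, 9-population, 4-temperature
design for species B); 36 species with 5 wings each. Trait scales:
tr(D) = 1.15 × 10⁻⁴ (9.3 × 10⁻⁵ for species B); tr(E) set so the FA
interaction F is ≈ 27 at two replicates; tr(P_ind) set so FA is ≈ 8% of
total shape variation; tr(G) = 3 × 10⁻⁴ (broad-sense, line level);
tr(R) = 5.88 × 10⁻³ — note R is a Brownian *rate*, so realised
among-species disparity on a Grafen cladogram is this trace times the
tree-dependent factor (mean diag S − mean S), ≈ 0.4 here.

The defining feature of the study system is that D, P, G and R share
principal structure — that is precisely what the common-subspace r²
measures — so the generating matrices share one random orthonormal basis
of the shape subspace, with log-spectra related to D's
(λ_i ∝ 0.7^i over rank 9) by ln λ_X,i = b·ln λ_D,i + ε_i. The slopes b
and the noise variances (set from the target squared correlation) use
the study's reported values: D–D across species 0.65/0.90, P 1.10/0.83,
G 1.27/0.83, second-species G 1.03/0.81, R 1.27/0.77. The base decay 0.7
keeps the ninth eigenvalue well above the measurement-error floor, which
is what makes rank 9–12 statistically supportable, as in the study data.
Deformation vectors are unit directions partially aligned with D's
leading axis (alignment fractions 0.68, 0.49, 0.30, 0.46 chosen to give
e_β shares of ≈ 24%, 15%, 9% and 14% of tr(D) against the 1/22 ≈ 4.5%
permutation null).

What the generator does **not** emulate: non-Gaussian FA or antisymmetry
(available only as a diagnostic target, not generated by default),
unbalanced replication within cells, digitizing-error correlations
between landmarks, missing landmarks, selection or Ornstein–Uhlenbeck
divergence, and phylogenetic uncertainty. Passing tests therefore
demonstrate that the estimators recover the truth under the assumed
model at the study's design sizes — not robustness to violations of
those assumptions in real data.

## Numerical conventions

* Permutation p-values: (1 + #{null ≥ observed})/(n_perm + 1); seeds are
  explicit arguments everywhere.
* CovMatrix validation: symmetry to 1e-8 relative, eigenvalues ≥
  −1e-8·λ_max; numerical rank counts eigenvalues above 1e-8·λ_max.
* Landmarks are 0-based internally, 1-based in files; matrix CSVs carry
  '#'-prefixed metadata (label, taxon, rank, scale factor) and
  x1,y1,…,x11,y11 headers.
* Degenerate inputs: coincident landmarks raise a singular-configuration
  error; zero ln CS variance refuses allometry control; individuals with
  one side are excluded with a warning and counted; constant β makes the
  shuffle null degenerate and errors.
* Problem sizes in the test suite and acceptance run are scaled to the
  study designs (n = 87/96/74 lines/36 species) except where a check is
  about estimator consistency, which uses n = 1,000 individuals (D),
  240 lines (G), and six replicate 36-species datasets with 20 wings per
  species (R — with few wings per species the structured individual
  variation leaks into the rate estimate through the diagonal-error
  approximation).

## Known limitations

* All REML designs assume balance (equal replicates per cell/line/
  species); unbalanced data must be subsampled or balanced upstream.
* The phylogenetic model's residual is diagonal; strongly structured
  within-species variation biases R at small within-species sample
  sizes (see above).
* Reduced-rank fits shrink trailing dimensions; comparisons are
  restricted to AIC-supported dimensions for exactly this reason, and
  log-variance regressions including unsupported dimensions are
  meaningless.
* The common-subspace r² of *estimated* matrices is attenuated by
  estimation noise relative to the population value; confidence limits
  from REML-MVN draws reflect that sampling variation but not rank-
  truncation bias.
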