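# Methods

This note records the models implemented in `statusflow`, their
assumptions, the defaults that matter, and what the synthetic generators do
and do not emulate.

## Synthetic cohorts (`statusflow.datasets`)

Cohorts follow the study design the package targets: five patient groups
(CTRL, active/quiescent Crohn, active/quiescent UC), 8 biopsies per group
(40 samples), two replica cohorts, with the status trait coded
S = 0 (control), +1 (active), −1 (quiescent). Expression is a latent-factor
model: a planted module of size m has a factor
`f = ρ·ẑ(S) + √(1−ρ²)·g` whose *sample* correlation with S is exactly ρ
(g is residualized against S), and members
`x_i = a_i f + a_i √((1−r²)/r²)·σ·ε` with loadings `a_i ~ U[0.5, 1]`,
so the factor explains the configured fraction r² of each member's variance
at the default noise scale σ = 1 and the module is exactly rank 1 at σ = 0.
Memberships and loadings are shared across replicas (the preservation
ground truth); factors and noise are drawn independently per replica.
Background proteins are independent Gaussian noise.

What this does *not* emulate: LC-MS/MS intensity distributions,
missingness, batch effects, or correlated background structure. Passing
tests therefore demonstrate correctness of the statistics on a clean
factor model, not robustness to real proteomic artefacts. The real data's
noise model is unknown; the factor model is an assumption, stated as such.

Default desk scale is 500 proteins (study scale, 3910, is one config field
away); all randomness flows through a single seeded generator per call.

## Co-expression analysis (`coexpression`, `preservation`, `enrichment`)

Unsigned adjacency `|cor|^ξ` is the default (a signed variant
`(0.5+0.5 cor)^ξ` is a config flag); the same power enters protein
significance `PS = |cor(x_i, S)|^ξ`. ξ defaults to 6 and can be selected by
the scale-free criterion: connectivities are binned into 10 equal-width
bins and log₁₀ frequency is regressed on log₁₀ mean connectivity; the
smallest power with R² ≥ 0.85 and negative slope wins, else the best-R²
power with a warning. Equal-width (not quantile) bins matter: integer-tied
degree distributions collapse quantile bins and flatten the curve.

TOM follows the standard unsigned formula
`TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij)`. Modules come
from average-linkage clustering of `1 − TOM` with a fixed-height cut at a
quantile of the merge heights — a deterministic, testable simplification
of dynamic branch cutting. The
default quantile is 0.5 (the median merge height): in noisy data the
module branch of the dendrogram completes early while background pairs
merge near height 1, so the median separates them cleanly; higher cuts
absorb background proteins into modules. Clusters below `min_module_size`
(default 30) are assigned to the grey module 0. Labels are renumbered by
decreasing size, making the partition invariant to protein order.

Eigengenes are leading right-singular vectors of the standardized module
submatrix, unit norm, sign-oriented to correlate positively with members.
The eigengene network uses `A = 0.5 + 0.5·cor`, `diss = 1 − cor`
(so `A = 1 − diss/2` exactly).

The smoothness functional returns `S(f) = Σ_{i~j} w_ij (f_i − f_j)²` over
unordered pairs, which equals `fᵀLf` (and half the ordered-pair sum).

**Zsummary.** For each reference module, two density statistics (mean
within-module adjacency, mean absolute within-module correlation, both in
the test cohort) and two connectivity statistics (reference-vs-test
correlation of intramodular connectivity and of module membership) are
compared to a null of random same-size protein sets in the test cohort
(≥ 50 permutations enforced; 100 by default). `z_density` and
`z_connectivity` are the medians of their family Z scores and Zsummary is
their mean. This is a reduced version of the full composite from the
module-preservation literature that keeps its median/mean structure; the
>10 / <2 interpretation thresholds carry over. On single-module synthetic
data the connectivity Z can sit near zero even for a perfectly planted
module — random sets that happen to contain module members inherit high
connectivity correlation, inflating that null — while the density Z is
enormous; the composite mean remains far above 10.

Candidate selection keeps members of preserved (Zsummary > 10),
status-correlated modules with PS ≥ 0.005 and |MM| ≥ 0.5 by default. PS is
on the ξ-power scale: 0.005 at ξ = 6 corresponds to |cor(x, S)| ≈ 0.41. At
these defaults ≥ 90 % of planted drivers are recovered with essentially no
false positives on the default synthetic cohort. Over-representation
analysis is a generic one-sided hypergeometric tail on user-supplied GMT
sets with Benjamini–Hochberg adjustment; it does not reproduce any live
annotation database.

## Manifold geometry (`manifold`)

Kernels: Gaussian `e^{−‖x_i−x_j‖²/h}` (σ parameterization maps to
h = 2σ²), sigmoid `tanh(x_i·x_j/N + c)`, rational quadratic
`1 − d²/(d² + c)`. The graph Laplacian is unnormalized, `L = D − W`;
embeddings solve the generalized problem `Lf = λDf` with a dense symmetric
solver, dropping one trivial mode per connected component; coordinates are
D-orthonormal.

The per-sample scalar field built from candidate proteins weights the
standardized candidate rows by PS, takes the leading right-singular
vector, and (optionally) maps the score through a Gaussian kernel centered
on the mean score of the control samples. Several final compositions would
be defensible; the status-centered kernel is this package's documented
choice.

**Singularity geometry.** The intersection set is estimated as points
whose k-nearest neighbourhood contains both sheet labels — simple and
oracle-checkable on the synthetic clouds. x₀ is refined by projecting the
query onto the affine subspace through the centroid of that set, spanned
by the near-common directions of the two local-PCA tangent spaces (the
centroid is unbiased for an affine intersection; curved intersections
would need a local centroid and are a known limitation). θ is the largest
principal angle between tangent spaces by default; alternatives
(`kl`, `fixed`) are config options, since more than one definition of the
incidence angle is defensible. D₁/D₂ are closed-form KL divergences
between Gaussians fitted to the two status groups' projections on n₁/n₂ —
the divergence is specified, the Gaussian density model is our choice.

The empirical point-cloud Laplacian uses the normalization
`L_{n,h}f(x) = (1/(n·h·(πh)^{d/2})) Σ_j e^{−‖x−x_j‖²/h}(f(x) − f(x_j))`
(positive-semidefinite sign convention). The leading-order prediction near
an intersection is `(1/√h) π^{d/2} r e^{−r² sin²θ} p(x₀)(∂n₁f₁ + cosθ ∂n₂f₂)`
with the dimension exponent generalized from the study's d = 8 to the
model's d; for edge-type singularities (the manifold sharply changes
direction, one-sided boundary limit) the second term is dropped — an
approximation flagged as such. The 1/√h blow-up is the
normalization-robust quantity the tests target: on d=2 sheets in R³ with a
piecewise-linear field, the fitted log–log slope over h ∈ [0.01, 0.08]
(averaging 9 query points along the intersection, 5000 points per sheet)
is −0.50, and the radial profile correlates ≥ 0.8 with `r e^{−r² sin²θ}`.
Below h ≈ 0.005 at this sampling density the Gaussian neighbourhood holds
too few points and the estimate degrades — bandwidths should keep
`n·(πh)^{d/2}·density ≫ 1`. The lumped constant C is fitted by least
squares of the empirical values against `(1/√h) r e^{−r²}` along the
reaction coordinate.

## Status dynamics (`dynamics`)

A single force term `C x e^{−x²}` cannot produce two stable fixed points
with an interior basin boundary at −0.08, so the force field is a
superposition of one Gaussian-localized term per status manifold,
and the potential is defined as `P = −∫F(x,0)dx` (closed form),
so `E = v²/2 + P` obeys `dE/dt = −ηv²` exactly. Default calibration:
wells μ = −0.75 and +0.75, amplitudes −1 and −ρ*, ρ* ≈ 1.0262 solving
`F(−0.08, 0) = 0` by root bracketing, h = 1, η = 0.1 — the fewest free
constants that reproduce the bistable portrait with the boundary at −0.08.
All five numbers are config-overridable; scaling both amplitudes (e.g. by
a fitted |C|) moves no equilibrium.

Equilibria come from sign-change bracketing on a 10⁴-point grid plus
Brent refinement to 1e−12, classified by the eigenvalues of
`[[0, 1], [∂F/∂x, −η]]` (the interior root is a saddle). Integration uses
RK45 with rtol 1e−10 / atol 1e−12 by default — tight because the control
stage certifies distances of order e^{−20} ≈ 2e−9. With η = 0.1 the two
basins interleave as spirals in (x, v): a rest start at −0.7 overshoots the
shallow saddle and lands in the control basin, while starts near the
disease well bottom (−0.5 … −0.15) stay diseased; the basin boundary
restricted to a neighbourhood of the saddle on the v = 0 axis is the
saddle itself. "Escape" (the white region of basin maps) is declared when
|x| exceeds the radius where |F(x,0)| < 1e−6 with outward velocity: with a
Gaussian-tailed force and η > 0 literal escape to infinity is impossible,
so this is the practical unbounded-orbit criterion.

Dissipation η is fitted by re-integrating each orbit from its initial state
at candidate η and minimizing the summed squared state error (bounded
scalar search); uncertainty comes from bootstrap over trajectories
(default 100 resamples) with percentile intervals. Noiseless orbits
recover η = 0.1 to ~1e−10; at observation noise 0.01 the 95 % interval
covers the truth. The reduction of the high-dimensional embedding to the
1-D coordinate is an open modelling choice: the intended hook is the
signed position along the axis joining status-group centroids, and the
dynamics module accepts any user-supplied calibration.

## Compensatory control (`control`)

The rescue loop follows the closest-approach linearization scheme of
compensatory network control: variational matrix by joint integration of
`dM/dt = DF(x(t))·M` (validated against the matrix exponential at fixed
points and central finite differences of the flow map), closest approach
refined by quadratic interpolation of the squared-distance series and
evaluated on the dense solution, and a per-iteration step from an SLSQP
solve of the linearized objective under the magnitude annulus
`ε₀ ≤ |δ| ≤ ε₁` (defaults 1e−4, 0.3), frozen components, optional boxes,
and the non-backtracking constraint `δ·δ_prev ≥ 0`. Steps that fail to
reduce the closest-approach distance are halved (never below ε₀); success
requires the *unperturbed* continuation of the current state to relax into
the target attractor, and the reported final distance is that
continuation's closest approach over an 800-time-unit horizon. The
"feasible target" for the distance certificate is interpreted as the
target stable state itself. The controller operates on the reduced state
space (2-D here, n-D supported); mapping perturbations back to named
proteins is descriptive only.

## Problem sizes used by the default test run

Cohorts of 500 proteins × 40 samples with one planted 60-protein module;
point clouds of 2000–5000 points per sheet in R³; 100-permutation
preservation nulls; 20-rescue batches. These desk-scale defaults exercise
every code path; study-scale parameters (3910 proteins, d = 8 sheets in
R²⁰) are reachable through the same configs.
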