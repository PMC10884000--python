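# Methods

This note records the modelling choices behind `fetalmorph`: the procedures,
their assumptions, the parameters that matter, what the synthetic generator
does and does not emulate, and the numerical conventions.

## Mesh preprocessing

Meshes are triangulated open surfaces in millimetres. The canonical frame is
fixed by rigid Procrustes alignment of four landmarks (both eyes, nose tip,
lip midpoint) to a reference set: y-up, face looking towards +z. Alignment is
refined by point-to-point ICP (k-d-tree nearest neighbours, no trimming,
best-iterate tracking so the mean nearest-neighbour distance is
non-increasing). Outward normals follow counter-clockwise winding; the
face-cropping step removes triangles behind a cutting plane or whose normals
deviate from the plane normal by more than a configured angle, keeping the
largest connected component. The default plane derives from the landmarks
(through the eye midpoint pushed 5 mm against the facing direction, normal
along the facing direction, 120° angle limit) because no numeric convention
for the crop exists a priori; it is exposed as configuration.

Isotropic remeshing is edge-based (long-edge split at 4/3 of the target,
short-edge collapse below 4/5 with link-condition and boundary checks,
valence-equalising flips, tangential Laplacian smoothing with back-projection
onto the input surface). Boundary vertices stay on the boundary curve. The
target edge length plays the role of a mesher's triangle-size control; 2 mm
is the intended operating point for face meshes, and output fidelity is
checked by Hausdorff-style distance rather than by a facet-distance parameter.

## Growth model and size normalisation

The size surrogate is `2√π (λ₁λ₂)^¼` from the two leading eigenvalues of the
vertex covariance (divisor n−1). The constant — the area of an ellipse with
two-standard-deviation semi-axes — is cosmetic: rescaling uses only ratios,
which a test verifies directly. The covariance route is preferred over raw
mesh area because cropping systematically changes the latter.

Quantile regression is solved exactly as the pinball-loss linear program
(HiGHS); statsmodels' IRLS implementation is used as an independent
cross-check in the tests, not in the fit. At τ = 0.5 LP optimality brackets
the number of non-positive residuals around n/2 with at most the number of
interpolated points (the polynomial order + 1) of slack. Quantile crossing is
repaired at evaluation time by sorting the three predicted values; raw
coefficients are preserved. Ages are modelled in weeks on 24–34; a warning is
emitted outside that range. Rescaling is isotropic about the vertex centroid
by `median(reference 29 wk)/median(ga)`.

## Deformation model

The kernel is `K(x,y) = exp(−‖x−y‖²/λ_V²)` — no factor 2 in the exponent —
stated once and used everywhere. The default integration uses a single time
step, i.e. a pure displacement by the momentum field: the downstream
statistics consume time-0 momenta only, so the statistical structure is
identical while registration gradients stay analytic and cheap. Full
geodesic shooting of the point-kernel Hamiltonian system
(`ċᵢ = Σ K aⱼ`, `ȧᵢ = (2/λ_V²) Σ K (aᵢ·aⱼ)(cᵢ−cⱼ)`, first-order Euler) is
available via `n_time_steps`; the sign of the momentum equation is the one
that conserves the Hamiltonian `H = ½ Σ aᵢ·aⱼ K(cᵢ,cⱼ)` under this kernel
convention, verified by a step-halving drift test.

The data term is a varifold metric
`⟨A,B⟩ = Σ_pq K(x_p,x_q; λ_W)(u_p·u_q)² s_p s_q` over cell centers, unit
normals and areas. Normals enter squared, so the metric is insensitive to
inconsistent winding from segmentation exports — the reason a varifold was
chosen over an orientation-sensitive currents term. Registration minimises
`d_W(warp(T,a), target)/σ² + Σ aᵢᵀK(cᵢ,cⱼ)aⱼ` with analytic gradients
(varifold gradient with respect to vertices chained through the displacement
model) under L-BFGS-B — a line-search gradient method chosen over plain
backtracking gradient descent for its robustness at a few hundred
parameters; finite differences back the `n_time_steps > 1` path. The
data-term weight `noise_std` defaults to 1 mm; no attachment-term convention
is inherited from elsewhere, so both the term and its weight are explicit
configuration.

## Atlas estimation

Control points start on a regular grid over the population bounding box with
one spacing of padding (per axis `floor(extent/spacing) + 3` points; spacing
defaults to λ_V). Template initialisation is a reproducible surrogate for a
manual step: the subject whose size is closest to the population median, 10
iterations of λ = 0.5 Laplacian smoothing, optional isotropic remesh.
Estimation alternates per-subject registrations (warm-started) with L-BFGS
template-vertex updates on the summed data terms; the recorded total energy
is asserted non-increasing over outer iterations on every synthetic run.

Filtering drops control points whose across-subject momenta variance (summed
over the three coordinates; summed rather than per-coordinate, a declared
convention) is below 10⁻⁴ of the maximum point variance. Empirically, with a
unit-noise varifold weight the fitted momenta carry a small halo around the
surface: relative variance is ~2·10⁻⁴ at 3λ_V from the face and ~10⁻⁷ at
4λ_V, so the guaranteed-inert zone starts at about 4λ_V. Filtering changes
reconstruction error by well under 1%.

Resolution selection uses AIC = 2k − 2 ln L̂ with k = 3 × retained control
points and ln L̂ from an isotropic zero-mean Gaussian model of vertex
point-to-surface residuals (σ̂ by maximum likelihood). This likelihood is a
declared convention — reconstruction residuals are not literally independent
Gaussian draws — and AIC rankings should be read comparatively, not as
calibrated evidence.

## Momenta statistics

PCA is the SVD of the column-centred momenta matrix. Pointwise tests treat
each control point's 3-D block as the response: Hotelling t² with pooled
covariance (divisor n₁+n₂−2) for two groups, and the multivariate-Gaussian
LRT `n·ln(det Σ̂₀/det Σ̂₁)` for general designs, which is a monotone function
of t² for a single binary regressor (verified numerically). 3×3 covariances
with condition number above 10⁸ receive a ridge of 10⁻⁸·tr(S)/3 — at small n
these matrices can be singular — and cells that remain singular are flagged
rather than silently zeroed.

Family-wise error over control points uses the permutation distribution of
the maximum statistic. Labels (or the tested covariate's values) are permuted
with a seeded generator; p = (1 + #{max_perm ≥ max_obs})/(N + 1), the +1
correction guaranteeing validity at any N. Label permutation, not residual
permutation, is used for regression tests — a known limitation when nuisance
covariates correlate with the tested one. Per-point empirical p-values
against each point's own permutation null are returned for mapping onto the
template; this realises the displayed "z-value" maps as exceedance
probabilities, since no sharper definition is available.

The permutation engine vectorises Hotelling t² over batches of labelings via
the identity pooled-scatter = total-scatter − n₁μ₁μ₁ᵀ − n₂μ₂μ₂ᵀ, which makes
400-dataset × 500-permutation calibration studies run in well under a minute.

## Shape scores

Score models are estimated from control (AGA) subjects only, at template cell
centers (per-cell normals, not vertices): mean momentum field m̄, covariance
Σ̄ and normal-projection SD σ̄ₙ, all with divisor N−1, so σ̄ₙ² = nᵀΣ̄n holds as
an algebraic identity and hence z_o² ≤ z_d wherever both are defined
(Cauchy–Schwarz in the Σ̄ metric). Σ̄ is inverted by symmetric
eigendecomposition with the shared ridge policy. Under a Gaussian null z_d is
χ²₃ (95th percentile 7.81, reported as 7.8) and z_o is N(0,1) (95% interval
±2); both calibrations are reproduced by Monte Carlo in the tests and the
acceptance script. Real control cohorts are only approximately Gaussian in
momenta space, so the reference bands are descriptive, not exact. New
subjects are scored by registering the (aligned, rescaled) mesh to the
template; no global "atypical subject" cutoff is defined — only per-cell
reference distributions.

## Monogenic module

Single-scale log-Gabor radial filter
`G(ω) = exp(−ln²(‖ω‖/ω₀)/(2 ln²σ_r))` with ω₀ = 1/wavelength and σ_r = 0.55,
zero DC; Riesz multipliers −iω/‖ω‖ give the odd part. The phase-asymmetry
threshold T ∈ [0,1] is dimensionless while |f_o| − |f_e| carries intensity
units, so T is scaled by the volume-median amplitude Ā (numerator
`max(0, |f_o| − |f_e| − T·Ā)`), keeping the map invariant to global intensity
scaling; ε defaults to 10⁻³·Ā. A single scale (configurable wavelength) is
used rather than a multi-scale bank. T = 0.5 is the default operating point.

## Synthetic population generator

The generator is the ground-truth supplier for every stage. Its defaults
define the study conditions: 135 subjects, ages uniform on 24–34 weeks, true
median size `g*(ga) = 60·(1 + 0.035(ga−29) − 0.0006(ga−29)²)` mm in surrogate
units (≈3.5%/week growth with mild deceleration, matching the template's own
surrogate size at the reference age), two latent shape modes with momenta SDs
3 and 1 mm (a 9:1 variance split), an age drift of 0.25 mm/week along a fixed
unit field, an FGR subgroup (disabled by default; fraction ≈0.13 in
case-control runs) with size factor 0.85 and a 2 mm localised momenta offset,
multiplicative lognormal size noise (σ = 0.03) and 0.2 mm vertex noise along
normals. Latent fields are white noise on the control grid smoothed by the
λ_V kernel and Gram–Schmidt orthonormalised — the same RKHS smoothness class
as the deformation model — and age/group effects are injected in momenta
space so recovery tests have a truth in the model's own parameterisation.
Each mesh is scaled so that its size surrogate equals the recorded true size.
All randomness derives from one seed with per-subject counter sub-streams.

What the generator does *not* emulate: ultrasound speckle and shadowing,
segmentation artefacts, anisotropic growth, non-Gaussian shape variation,
missing data and pose variability in acquisition. Passing tests therefore
demonstrate correctness and calibration of the machinery under the stated
generative assumptions, not clinical performance.

## Problem sizes and numerical conventions

Test and example runs use coarse settings chosen as the package's own desk
scale: template grids of 16×18 to 32×36 vertices, control-point spacings of
14–22 mm, cohorts of 6–500 subjects depending on what a check needs, 100–1000
permutations, and 10⁶ Monte-Carlo draws for score calibration. Registration
uses up to 150 L-BFGS iterations (gtol 10⁻⁶); duplicate vertices are merged
at 10⁻⁹ mm; degenerate triangles are dropped at construction; the quantile
LP uses HiGHS defaults. Ill-conditioned covariance handling (ridge at
condition 10⁸, γ = 10⁻⁸) is shared between the statistics and score modules.

## Known limitations

- The single-step displacement default is not a diffeomorphism guarantee for
  large momenta; use `n_time_steps > 1` for fidelity studies.
- AIC values depend on a convention for the residual likelihood (above).
- Label permutation for regression tests; no residual permutation scheme.
- The remesher is a practical edge-based scheme, not a guaranteed-quality
  mesher; extremely anisotropic inputs may need more iterations.
- Score reference bands assume Gaussian momenta; heavy-tailed real cohorts
  will show more than 5% of cells beyond the nominal bounds.
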