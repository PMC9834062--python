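# Methods

## The model

`smlmfit` fits parameterized geometric models to single-molecule
localization microscopy (SMLM) coordinates by maximum likelihood.  The
data of one *site* (a bounded box containing one structure) are K
localizations `l_k = {x_k, σ_k}`: a coordinate in nm and a per-axis
precision (standard deviation of the coordinate estimate).  A geometric
model `f(p)` describes the expected fluorophore geometry; from it a
probability density `M(x, σ | p)` is constructed and the site
log-likelihood is

    LL(p) = Σ_k ln M(x_k, σ_k | p),

maximized over the model's intrinsic parameters (shape) and extrinsic
parameters (translation x0, z-y-x rotation angles α, β, γ, optional
per-axis scale, extra uncertainty ε, background weight w_bg).

For a model given as J fluorophore positions `v_j` with weights `q_j`,

    M(x, σ | p) = (Σ_j q_j)⁻¹ Σ_j q_j (2π)^(−D/2) det(Σ)^(−1/2)
                  exp(−½ (x − v_j)ᵀ Σ⁻¹ (x − v_j)),

with the per-localization covariance
`Σ = diag(σ_x² + ε², …)`.  The normalizing exponent is `−D/2` so the PDF
integrates to 1 in both 2D and 3D.  The extra uncertainty ε absorbs blur
the precision does not describe (linkage error, drift, small unmodeled
deformations).  Localizations not explained by the structure are absorbed
by a uniform background `M_bg = d^(−D)` over the site of side d, mixed
with weight w_bg; from it the background count `K_bg = K·w_bg` and
density `ρ_bg = K_bg/d²` follow.  Composite models are convex
combinations of sub-model PDFs sharing one background; sub-model poses
are expressed relative to the first component.  Multi-color data evaluate
each channel's PDF only on that channel's localizations, with an optional
per-channel exponent `w_c = K_c⁻¹ Σ_c K_c` balancing unequal counts
(default `w_c = 1`).

Continuous models (curves/surfaces) are discretized at a maximum point
spacing δ < 0.75 × the smallest (clamped) precision component, with
weights inversely proportional to the local sampling density; a
`sigma_min` clamp coarsens the sampling for speed.  Density-image models
are normalized over their grid, convolved with a Gaussian of SD
`sqrt(⟨σ⟩² + ε²)` per axis (mean precision, not per-localization), and
interpolated multilinearly.  Poses enter continuous/image models by
reverse-transforming the data, `x' = R⁻¹S⁻¹(x − x0)`, and discrete models
by forward-transforming the points, `v' = SRv + x0`, keeping the
anisotropic Gaussians axis-aligned in the frame where the blur is
defined.  An alternative objective, the cross-correlation score
`L_cc = Σ_k M(x_k, σ_k | p)`, is selectable.

Model comparison uses the small-sample Akaike criterion,
`AIC = 2P − 2 ln L̂` and `AICc = AIC + (2P² + 2P)/(K − P − 1)` with K the
number of localizations; for visual comparison AICc is normalized by K.
Confidence intervals come from sampling the log-likelihood near the
optimum and least-squares fitting the quadratic model
`LL_q(p) = ½ (p − p̂)ᵀ H (p − p̂) + a0`; the b-th parameter variance is
`[(−H)⁻¹]_bb` and `CI = p̂_b ± 1.96 √var`.  The conventional ½ makes H
the Hessian, so the Gaussian-location problem recovers the Fisher limit
var = 1/n.  Sampling uses 20·P(P+3)/2 points uniform within ±2% of each
bound range; if −H is not positive definite the CI is flagged and a
pseudo-inverse used.

## Built-in models

* `npc_dual_ring` — two continuous parallel rings (radius r, separation
  s) in planes z = ±s/2; the model origin is the pore center.
* `npc_discrete` — n-fold symmetric corners (default n = 8) with two
  fluorophore copies per unit per ring (32 positions), ring twist θ
  between the rings.  The two copies sit at ±7° about the corner angle
  (the intra-unit offset is not resolvable at fit time and is exposed as
  a constant, default 14° total).  γ and θ are only identifiable modulo
  2π/n and are reported in a canonical sector.
* `npc_elliptical` — elliptical variant with ellipticity e = 1 − b/a and
  mean radius r = (a + b)/2 (so a = 2r/(2 − e)), plus the internal
  rotation Φ of the long axis.
* `mt_spline` / `mt_tube` — a natural cubic spline through an odd number
  N of control points built outward from the middle point (distance h,
  azimuth/elevation per point), chord-length parameterized; the tube
  renders rings perpendicular to the local tangent.  The natural end
  condition is our choice; "piece-wise third-order polynomial" leaves it
  open.
* `endocytic` — 2D two-channel model of a yeast endocytic site: the
  projection of a hemiellipsoid surface (half-axes a along the
  invagination axis, b lateral; channel 0) and of a thick ring (inner and
  outer radii, thickness; channel 1).  The ring projection uses the
  closed-form chord-length marginalization; the hemiellipsoid surface
  area element is integrated numerically on a parameter grid.  The
  hemiellipsoid base offset is bounded ≥ 0 (at/above the ring plane).
* `line_segments` — a discrete model whose points are the N vertices of
  connected segments, positioned like the spline control points.

## Fitting strategy

Optimizers: a seeded differential-evolution global search, a
Nelder–Mead simplex (with a bound-scaled initial simplex — the default
one degenerates for parameters starting at zero), and L-BFGS-B.  Chains
pass estimates from one step to the next as initial values; the standard
NPC chain is smooth fixed-radius dual ring (global) → free dual ring
(simplex) → discrete corners (simplex), with a coarse (γ, θ) grid scan
before the last step because the ring steps are blind to both angles.
Fit parameters carry physiological windows (r ∈ [30, 80] nm,
s ∈ [20, 100] nm for the pore) which keep rare sites with one sparsely
labeled ring from collapsing onto a single-ring solution.  Sites with
fewer than P + 2 localizations are refused.  Densities are floored at
1e−300 before logs (flagged), keeping the objective finite.

## Simulator

A two-state (bright/dark) fluorophore model with bleaching: model
positions → Bernoulli labeling (`labeling_prob`) → per-label Gaussian
displacement (`extra_displacement_sd`; linkage error/drift proxy) →
exponential on-times of mean `mean_on_time` starting at uniform random
times, geometric reactivation (`reactivation_prob`, mean blinks
1/(1 − p)) → per-frame Poisson photons proportional to the on-fraction →
per-axis precision from a pluggable rule (default analytic Gaussian-PSF:
σ_xy = 130 nm/√photons, σ_z = 2σ_xy; the axial factor matches near-focus
astigmatic calibrations) → Gaussian coordinate noise.  By default the
per-frame localizations of one blink are merged into a single
localization (precision-weighted position, photons summed, precision
from the total) — the frame-grouping every real processing pipeline
applies before fitting, so the simulator's output is the same kind of
table a fitter actually sees.  Without merging, the ~4–5 strongly
correlated raw localizations per label measurably bias the separation
estimate (≈ −1 nm) through a tilt/separation degeneracy; set
`merge_blinks=False` to study that regime.  Blinks below `min_photons`
(default 50) are dropped, standing in for the quality filtering of real
pipelines.  Uniform false localizations can be injected at a rate
`bg_density` per nm^D.  The default photon budget (6,500 photons/s at
30 ms frames) realizes a mean lateral precision near 10 nm.

What the simulator does *not* emulate: camera-frame image formation,
multi-emitter overlap, frame-to-frame merging of localizations, drift
beyond a Gaussian displacement, or dye-specific dark-state kinetics.
Passing the validation studies therefore shows the estimators are
correct under the stated generative model, not that every real-world
artifact is handled.

## Validation studies and their conditions

All studies use the experimentally determined mean pore geometry
(r = 53.4 nm, s = 50.2 nm, θ = 8.8°) as ground truth, random poses
(tilt ≤ 15°, uniform in-plane rotation, ±20 nm center offsets), a weak
uniform background, and discard sites with < 30 localizations.

* **Parameter recovery** (200 sites): ~10 nm lateral precision, 6.4 nm
  label displacement, 80% labeling.  The well-labeled regime is
  deliberate: at 60% labeling the known sparse-ring mechanism biases the
  mean separation low by ~1.5 nm — a property of the data, not the
  estimator.  Twist errors are evaluated modulo the 45° symmetry sector.
* **Symmetry selection** (100 sites, candidates 6–10-fold): bright
  localizations (~4.5 nm lateral precision) and a small 3 nm label
  displacement, emulating merged and precision-filtered experimental
  data.  At 10 nm precision with 6.4 nm per-label displacement the
  symmetry signature is not identifiable — wrong-symmetry models then
  beat even truth-initialized correct fits, an effect of unmodeled blink
  stoichiometry (a probabilistic blink model is out of scope).
* **Model-free averaging** (150 particles, 60% labeling, n = 50 subset,
  stop after J = 3 non-improving iterations): same bright conditions,
  for the same reason — the registration likelihood's optimum moves off
  the true pose at 10 nm precision.  Registration uses a coarse in-plane
  rotation grid (48 angles) plus simplex refinement of the best 3
  candidates, a 3 nm extra blur that smooths the rotational likelihood
  (damping corner "hot spots"), a 2,500-point template subsample
  (configurable; the mixture cost is O(J·K)), and a numba-compiled
  kernel that truncates contributions below exp(−34).  The fused average
  is aligned to its own symmetry frame by a dual-ring refit before the
  azimuthal harmonic spectrum is read.
* **Depth-distortion correction** (30–36 sites over ±400 nm of depth):
  a synthetic axial compression with local rate 0.93 + 8·10⁻⁸ z² (≈7%,
  the experimentally observed scale).  The distortion remaps the
  measured z axis, so both the scatter and the reported σ_z are
  compressed in the synthetic data; conversely the correction rescales
  σ_z by the local factor s_f(z) (first-order error propagation).
  E(z) is obtained by trapezoidal quadrature of s_f on a 1 nm grid.

Problem sizes (200/100/150/30) are scaled down from the thousands of
sites of a full experimental replication; they keep each study's Monte
Carlo error a few times below the tolerance it is compared against.

## Numerical choices and conventions

* Lengths nm; angles radians internally, degrees at the CLI boundary;
  right-handed coordinates with z = 0 at the focal plane; closed site
  boxes; 0-based rows.
* Rotation matrix: R = Rx(α)·Ry(β)·Rz(γ) (rotations about z, then y,
  then x); `angles_from_matrix` takes β ∈ [−π/2, π/2].
* Discretization requests 99% of the δ bound so the achieved spacing is
  strictly below it; a model needing more than 2·10⁶ points raises a
  resource error advising a larger `sigma_min`.
* Image-model blur uses edge-replicating convolution (a uniform density
  stays exactly uniform) and renormalizes over the grid afterwards.
* Circle fits (segmentation): algebraic Kåsa least squares plus one
  Gauss–Newton step; the fixed-radius center refit iterates Gauss–Newton
  to convergence.
* Segmentation defaults: 5 nm render pixels, 55 nm ring kernel with
  10 nm Gaussian SD normalized to unit peak (the score reads as a
  ring-weighted count), non-maximum suppression over one pore diameter,
  greedy deduplication of centers closer than the kernel radius.
* Ties in similarity ranking and model ranking break by lower index
  (stable sorts); rank-1 is the particle with the largest row sum.

## Known limitations

* Localizations from the same fluorophore are treated as independent;
  the marginal model is correct but cluster-level correlations reduce
  the effective information and, at poor precision, bias ε downward and
  defeat symmetry discrimination and model-free registration (see the
  study conditions above).
* The continuous dual-ring model underestimates the ring separation by
  a few nm on corner-clustered data; the chain's final discrete step
  removes this, so separation values should be read from the full chain.
* Pairwise registration of two sparse particles is unreliable on its
  own; the pipeline relies on the dense template for accurate poses and
  uses pairwise scores only for ranking and seeding.
* `M_bg = d^(−D)` assumes cubic sites; non-cubic boxes would use the
  reciprocal box volume (not currently exposed).
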