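# Methods

This note documents the models and numerical choices in `boundaryprofile`,
what the synthetic-data generator does and does not emulate, and the
package's known limitations.

## Coordinate conventions and input assumptions

All surfaces and volumes live in one world RAS frame in millimetres; voxel
indices are 0-based and each volume carries its own invertible
voxel-to-world affine. Surfaces and volumes are assumed coregistered on
input; an optional affine argument lets users supply a registration.
Subjects share one template mesh, so vertex correspondence is by index —
spherical registration and template resampling are out of scope. Diffusion
and structural volumes may sit on different grids (e.g. 2.4 mm vs 1 mm);
sampling always happens in each volume's own voxel space through its
affine, never after resampling, to avoid double interpolation.

## Depth sampling

Two depth conventions coexist, matching standard surface-based practice:

* **Gray matter** (projection fractions, e.g. 30% and 60% of cortical
  thickness): the sample point is `white + f·(pial − white)` along the
  white→pial vertex correspondence.
* **White matter** (absolute depths, e.g. −1, −2 mm): the sample point is
  `white + d·n̂` along the unit outward vertex normal (area-weighted
  average of incident triangle normals), with negative `d` pointing inward.
  Whether sub-boundary sampling should follow the normal or the extended
  white-pial axis is genuinely open; normal-based sampling is the default
  and an axis-based option exists.

Interpolation is trilinear (nearest-neighbour behind a flag for
sensitivity checks). Sample points outside the voxel-grid hull are masked
invalid, never clamped — silent clamping would bias statistics exactly at
the boundary, where the analysis lives. Masks propagate: a vertex invalid
at any depth it samples is excluded there, and validity can only shrink
with deeper sampling.

## Gray-white contrast

`GWC_i = 100 · (WMI_i − GMI_i) / (0.5 · (WMI_i + GMI_i))`, i.e. the
percentage intensity difference relative to the mean intensity, with WMI at
−1 mm and GMI at 30% CT. The expression is read as division by the mean
(the Salat-style contrast); a literal left-to-right reading of the formula
would not yield a contrast measure. GWC is defined only where both inputs
are valid and WMI + GMI > 0. For positive intensities GWC ∈ (−200, 200),
strictly increasing in WMI and decreasing in GMI. Smoothing is applied to
the GWC output (and each FA/MD depth map) before statistics; whether the
inputs should be smoothed instead is ambiguous in the literature, so
input-smoothing exists behind a flag (`smooth_gwc_inputs`) but is off by
default.

## Surface smoothing

Smoothing iterates `S = I + (α/d_max)(A − D)` on the valid-vertex subgraph
(A the 0/1 one-ring adjacency, D the degree matrix, α = 0.95 so diagonals
stay positive). S is symmetric with unit row sums, hence doubly stochastic:
constants and the mean over valid vertices are conserved exactly, masked
vertices neither receive nor contribute mass, and weights renormalize at
mask borders. The iteration count is calibrated per mesh by applying S once
to the coordinate maps and their squares, which measures the per-step
kernel variance exactly; the count is chosen so the accumulated in-sheet
variance matches σ² = FWHM²/(8 ln 2) per axis. On the regular 1 mm slab a
15 mm target yields a measured kernel FWHM of ~15.2 mm
(variance-of-kernel measurement). Geodesic distance is approximated by the
mesh graph; at 15 mm FWHM on ≈1 mm meshes the error is negligible, and the
kernel on a triangulated square grid is mildly anisotropic (the diagonal
direction is better connected) — acceptable at this FWHM, and irrelevant
to RFT inference, which measures smoothness from residuals rather than
assuming the nominal kernel.

## Vertex-wise GLM

`Y = β0 + β1 Group + β2 Sex + β3 Group×Sex + β4 Site + β5 Age + β6 Age² +
β7 FSIQ + ε`, fitted by OLS independently per vertex (vertices with any
non-finite observation are masked, not fatal). Categorical factors are
effect-coded (−1/+1): β1 is then half the group difference and β3 the
interaction, keeping main effects interpretable in the presence of the
interaction (the choice of coding is not dictated by the analysis it
reproduces). Continuous covariates are mean-centered across the full
sample; Age² is the square of centered age, itself centered, to limit
collinearity. Contrast t-maps are β̂/SE with pooled residual df; model
terms are assessed by step-up nested-model F-tests over the whole sample,
with a term retained when its F-map survives the same cluster-wise
correction as other maps (the retention rule is a package decision; the
single-column case satisfies t² = F exactly). Robustness reruns
(subject exclusion, extra covariates such as BDI or total brain measures)
are config variants of the identical pipeline, not separate code paths.

## Cluster inference

Local smoothness is estimated from residuals normalized to unit length per
vertex: for each edge of length d, λ = ‖u_i − u_j‖²/d² estimates the
variance of the field's spatial derivative, giving local
FWHM = √(4 ln 2 / λ) (for spatially white noise this is √(2 ln 2)·d).
Resels per vertex are vertex area / FWHM²; cluster extents are sums of
per-vertex resel densities, so nonuniform smoothness is absorbed into the
extent ("nonisotropic" correction) rather than a global smoothness value.

Suprathreshold clusters are connected components (vertex adjacency) of
|t| ≥ t_CDT computed separately per tail; the default cluster-defining
threshold is two-tailed p = 0.001, exposed as a parameter — RFT cluster
p-values are only calibrated at high thresholds. The corrected p is the
standard 2D t-field formulation: expected cluster count E_m from the
Euler-characteristic density at the CDT (doubled for two tails), cluster
resel extent exponential with mean E_n/E_m, and
p = 1 − exp(−E_m · e^(−s/E[S])). Degrees of freedom ≤ 2 are refused.

The permutation oracle uses the Freedman–Lane scheme: residuals of the
reduced (nuisance-only) model are row-permuted and added back to the
reduced fit, the full model is refitted, and the null distribution of the
maximum cluster resel extent yields empirical corrected p-values, floored
at 1/(n_perm + 1). Permuted-map extents reuse the observed smoothness
estimate (recomputing it per permutation changes nothing measurable and
triples the cost). On null smooth synthetic data both procedures hold the
family-wise error within [0.01, 0.10] at nominal 0.05 (200 datasets,
31×31-vertex slab, 80 subjects), and a planted 2-SD disc is detected with
Dice ≥ 0.5 in ≥ 18/20 replicates — these calibration sizes are the
package's test defaults and scale up trivially.

## Overlap statistics

Given two binary maps of cluster-significant vertices, the package reports
counts, the intersection, and the percent overlap relative to an explicit
denominator map (convention: the diffusion-measure map). Equal prevalence
of two alterations is tested with a 2×2 χ² on
[[n_A, N − n_A], [n_B, N − n_B]] with Yates continuity correction by
default — recomputation of published statistics from their printed counts
matches the corrected statistic and not the uncorrected one — with the
uncorrected variant behind a flag. The chance level of an observed percent
overlap comes from simulated random difference maps; two modes:

* **iid** (default): each simulation draws fresh vertex-wise random
  t-values (standard normal, or Student t given df) for both maps and
  thresholds at two-tailed p < 0.05. Under independence the expected
  percent overlap equals 100 × prevalence ≈ 5%.
* **prevalence-matched**: conditions on the observed suprathreshold
  counts. The intersection of two uniformly random vertex subsets of fixed
  sizes is exactly hypergeometric, and is drawn as such — equivalent to
  permuting both maps, at O(1) per simulation.

Neither mode models spatial autocorrelation of real statistical maps; the
simulated "random t-values" are vertex-independent, which makes the null
narrower than a smoothness-matched null would be. Spatially informed nulls
(spin tests, variogram matching) are deliberate non-goals.

The empirical p is (1 + #{sims ≥ observed})/(n_sims + 1), so it is never
zero and is floored at 1/(n_sims + 1) (2.0·10⁻⁴ at the default 5,000
simulations).

## Demographics and clinical correlations

Continuous group comparisons use Welch's unequal-variance t with
Welch–Satterthwaite fractional df (computable from summaries or raw data,
identically); categorical 2×2 tables use the continuity-corrected χ². Note
the vertex-wise GLM uses pooled OLS df while demographics use Welch df —
both conventions are standard at their respective stages and are not
harmonized. Clinical associations are Pearson correlations between
per-subject cluster means and questionnaire scores, computed within the
clinical group by default (scores are condition-specific), reported
uncorrected as exploratory with an optional Benjamini–Hochberg column;
pairs with under 3 complete observations or zero variance are reported
undefined rather than dropped silently.

## Synthetic cohorts

The generator emulates a two-group (ASD/TD), two-sex, two-site adult
cohort. Defaults are chosen to be realistic for such a sample: ages
uniform on 18–52 years, FSIQ ~ N(115, 11²), cortical thickness 2.67 mm
mean with 0.09 mm SD across vertices, T1 plateaus 110 (WM) / 90 (GM)
(boundary GWC ≈ 20%), FA 0.40/0.15, MD 0.70/0.85 (10⁻³ mm²/s), sigmoidal
transition of 0.5 mm 10–90% width, smooth noise (6 mm FWHM) plus a
subject-level offset, and an autism-trait (AQ-like) score correlated 0.6
with the subject's realized effect magnitude within the clinical group.
Effect magnitudes are expressed in units of the modality's reference noise
SD; a `scale` switch turns the applied noise off without zeroing effects,
so noise-free closed-form checks remain possible. Published analyses of
this kind report suprathreshold extents but not effect sizes in FA/MD
units, so planted defaults are calibrated to produce comparable
suprathreshold behavior, not to match unreported magnitudes.

The default test world is a flat slab (white surface at z = 0, pial
displaced by per-vertex thickness) because normals, sigmoid profiles, and
kernel FWHM have exact analytic expectations there; an icosphere variant
exercises curvature and closed-mesh conservation. The generator does *not*
emulate gyrification, scanner artifacts, partial-volume effects,
registration error, or realistic spatial covariance of effects — so
passing tests demonstrate correctness of the estimators and calibration of
the inference under the stated noise model, not robustness to real
acquisition physics.

Age affects volumes only through the cohort table by default (the β5/β6
terms then estimate null coefficients); a quadratic age-effect switch
exists to exercise them. A 2.4 mm diffusion-grid option reproduces the
structural/diffusion resolution mismatch for robustness tests.

## Numerical choices and degenerate inputs

* OLS via pinv; zero residual variance masks the vertex rather than
  producing infinite t.
* Rank-deficient designs are refused with the collinear columns named
  (QR diagnostic); a `check_rank` escape hatch exists for deliberately
  degenerate nested-model comparisons.
* Empty suprathreshold sets yield empty cluster tables, not errors.
* Out-of-volume samples, isolated vertices, and undefined correlations are
  all masked/NaN, never silently imputed.
* All randomness flows from a single seed through named substreams
  (SHA-256-derived, < 2³¹), so pipeline reruns are bitwise reproducible.

## Problem sizes used in the shipped tests

Calibration and power studies run on a 31×31-vertex, 30 mm slab with 80
subjects (40 per group, balanced over sex and site), 200 null datasets for
FWER, 100–500 permutations, and 200–5,000 overlap simulations; the
overlap-significance recomputation in `scripts/acceptance.py` runs at full
surface scale (327,684 vertices, 5,000 simulations). These sizes are the
package's defaults for its own verification and can be raised freely.
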