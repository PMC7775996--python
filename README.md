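# boundaryprofile

Surface-based analysis of diffusion metrics and T1 tissue contrast at the
gray-white matter (GWM) boundary of the cerebral cortex.

## The problem

The transition between cortical gray matter and the underlying superficial
white matter is a locus of interest in neurodevelopmental conditions: an
"indistinct" boundary — reduced intensity contrast, altered diffusion in the
U-fiber zone — is a candidate imaging signature. Characterizing it requires
sampling scalar volumes (fractional anisotropy FA, mean diffusivity MD,
normalized T1 intensity) at each vertex of a reconstructed cortical mesh at
several depths relative to the white surface, and testing vertex-wise group
effects with proper control of the family-wise error over hundreds of
thousands of correlated tests.

`boundaryprofile` implements that pipeline end to end for researchers in
surface-based morphometry:

1. **Depth sampling** — at each vertex *i*, volumes are sampled trilinearly
   at the boundary, at projection fractions of cortical thickness into the
   gray matter (30% CT, 60% CT along the white→pial correspondence vector),
   and at absolute depths (−1 mm, −2 mm along the inward surface normal)
   into the superficial white matter.
2. **Gray-white tissue contrast** —
   `GWC_i = 100 · (WMI_i − GMI_i) / (0.5 · (WMI_i + GMI_i))`,
   with WMI sampled at −1 mm and GMI at 30% CT; lower GWC = more "blurred"
   boundary.
3. **Surface smoothing** — each map is smoothed along the mesh with a
   heat-kernel approximation calibrated to a target FWHM (default 15 mm).
4. **Vertex-wise GLM** —
   `Y_i = β0 + β1·Group + β2·Sex + β3·Group×Sex + β4·Site + β5·Age + β6·Age² + β7·FSIQ + ε_i`
   with effect-coded factors and mean-centered covariates; contrasts are
   t-maps (β/SE) and model terms are assessed with step-up nested-model
   F-tests.
5. **Cluster inference** — nonisotropic random-field-theory cluster
   correction (local smoothness from normalized residuals, extents in
   resels), with a Freedman–Lane permutation test as an independent oracle.
6. **Overlap statistics** — counts and percentages of vertices altered in
   two measures, pairwise continuity-corrected χ² prevalence tests, and a
   simulation null (random t-value maps thresholded at two-tailed p < 0.05)
   for the chance probability of the observed overlap.
7. **Synthetic cohorts** — a generator producing template geometry,
   per-subject volumes with sigmoidal tissue profiles across the boundary,
   planted group and group-by-sex effects, smooth noise, and cohort tables
   with clinical scores, so every stage is testable with known ground truth.

Standard formats throughout: FreeSurfer binary surfaces / GIFTI, MGH/NIfTI
volumes, TSV tables (via nibabel and pandas).

## Worked example

```python
from boundaryprofile import (GroupSummary, welch_t, prevalence_chi2,
                             simulate_overlap_null)

# Welch t-test from group summaries (mean, SD, n per group)
t, df, p = welch_t(GroupSummary(92, 26.71, 7.20), GroupSummary(92, 28.38, 6.73))
print(f"age: t({df:.2f}) = {t:.2f}, p = {p:.2f}")

# are alterations in two measures equally prevalent across the surface?
chi2, p = prevalence_chi2(88131, 17046, 327684)
print(f"GWC vs FA prevalence: chi2(df=1) = {chi2:.0f}, p = {p:.3g}")

# chance level of a 53.59% overlap between two thresholded maps
sim = simulate_overlap_null(327684, observed_percent=53.59, n_sims=1000, seed=1)
print(f"mean chance overlap = {sim['mean_percent']:.2f}%, "
      f"p(overlap >= 53.59%) = {sim['sim_p']:.4f}")
```

prints

```
age: t(181.18) = -1.63, p = 0.11
GWC vs FA prevalence: chi2(df=1) = 57226, p = 0
mean chance overlap = 5.01%, p(overlap >= 53.59%) = 0.0010
```

The age difference is not significant; the χ² shows GWC alterations are far
more widespread than FA alterations; and a 53.59% overlap between two
thresholded maps is far beyond the ~5% expected if the two spatial patterns
were independent.

A full synthetic run (simulate → sample → GWC → smooth → GLM → clusters →
overlap → report):

```sh
boundaryprofile run --out myrun --seed 7
boundaryprofile report myrun
```

or from Python, `run_pipeline(PipelineConfig(out_dir="myrun", seed=7))`.
The run directory contains per-depth t-maps, a cluster table with
RFT-corrected p-values, overlap JSON, demographics, clinical correlations,
a resolved config snapshot, and a content-hash manifest (reruns are bitwise
reproducible).

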