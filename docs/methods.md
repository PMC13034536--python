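# Methods

## The marginal diffusion slope

The biomarker rests on the established negative relation between the
apparent diffusion coefficient (ADC) and tissue cellularity: densely
cellular tumour restricts water diffusion. At an infiltrating margin the
cell density decays gradually into surrounding brain, so ADC rises
gradually; at a circumscribed margin it rises sharply. The marginal
diffusion slope (MDS) measures that rise per millimetre along directions
normal to the macroscopic tumour surface, sampled centrifugally (inside
to outside).

### Surface-normal estimation

The enhancing-tumour mask is first regularized — morphological closing
(Euclidean ball, radius 1 voxel by default), hole filling, removal of
components below 5 voxels; every remaining focus is kept so multifocal
disease contributes all of its margins. Boundary voxels are mask voxels
with a face-adjacent background neighbour (4-/6-connectivity). At each
boundary voxel the boundary points inside a centred kernel (5×5 in 2D,
5×5×5 in 3D) are mapped to world millimetres and the scatter matrix
about their centroid is eigendecomposed: the leading eigenvector(s) span
the local tangent line/plane and the smallest-eigenvalue eigenvector is
the normal. This is the unique 3D generalization of the 2D
tangential/normal eigenvector pair, and doing the decomposition in world
coordinates makes anisotropic voxels metrically correct. Orientation is
fixed outward by the gradient of a Gaussian-smoothed (σ = 1 voxel) mask
indicator; where that gradient vanishes (a symmetric plate, say) the
normal points away from the component centroid. Kernels containing fewer
than 3 boundary points are degenerate; such vectors are skipped and
counted (on convex ROIs of realistic size the skipped fraction is
far below 1%). On a digitized sphere of radius 14–15 voxels the mean
angular error against the analytic radial direction measures ≈ 2°.

The same code path serves 3D clinical masks and 2D preclinical slices.

### Profile sampling, validity, and the slope fit

Each normal is sampled at arc positions from −2 mm (inside the boundary)
to +6 mm (outside) at 2 samples/mm — 17 samples — by tri-/bi-linear
interpolation in world space; positions outside the volume are marked
missing, never zero-filled or imputed. A sample is *measurable* when its
containing voxel belongs to the combined tumour-abnormality mask
(enhancing + non-enhancing core + FLAIR abnormality): the FLAIR class
alone would wrongly exclude the inner 2 mm, which lie in enhancing
tumour. The profile's contiguous run is the longest consecutive stretch
of measurable, non-missing samples containing the boundary crossing
(arc = 0); the profile is valid iff the run spans **strictly more than
4 mm**. Anchoring at the crossing reflects that the metric characterizes
the margin; missing samples break contiguity because interpolating
across unmeasured tissue would manufacture slope.

The slope is ordinary least squares of value against the *sample index*
over the run, multiplied by the sampling frequency (2 points/mm) to
express (mm²/s)/mm — numerically identical (to ≈1e-12 relative) to
regressing on the arc position directly; both paths are asserted in the
tests. Fits need ≥3 samples. The patient-level MDS is the unweighted
mean of valid profile slopes (no weighting information is available to
justify anything else); when no profile is valid the result is an
explicit NaN sentinel, never 0, because 0 is a meaningful slope. A
sigmoidal profile model was deliberately not used: with realistic noise
such fits are unstable, and the linear slope is the robust choice, at
the cost of underestimating steepness where the linear section of the
transition is narrow (see the fixture discussion below).

### Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `window_mm` | (−2, +6) | mm | sampling window relative to the boundary |
| `rate_per_mm` | 2 | 1/mm | sampling frequency (0.5 mm interval) |
| `min_contiguous_mm` | 4 | mm | strict lower bound on the measurable run |
| `closing_radius_vox` | 1 | voxels | ROI closing radius |
| `min_component_vox` | 5 | voxels | smallest focus retained |
| `kernel_vox` | 5 | voxels | normal-estimation kernel edge |

All distances are computed in world millimetres through the NIfTI
affine; the pipeline runs on whatever common grid the inputs share and
records it in the run manifest. 4D inputs are rejected rather than
squeezed — an ADC map is a single volume, and a silent squeeze would
hide conversion errors upstream.

## The simulator

### Sphere phantom

A scalar field `v(x) = v₀ + g·r(x)` with a co-centred ball ROI gives
every centrifugal profile the exact slope `g`, making the full pipeline
(boundary → normals → sampling → fit) testable against a closed form.
Recovered mean slopes agree with `g` to ≈0.1% at radius 15 mm on a 1 mm
grid; residual error comes from the ≈2° normal discretization error.

### Gaussian cellularity → diffusion model

Cellularity is `ρ(x) = ρ_peak · exp(−r²/2σ²)` on a 2D grid (256² at
0.5 mm); diffusivity follows Graham's relation `D_raw = 1/√(ρ + ρ_floor)`
and is rescaled so the far field equals the normal-parenchyma plateau of
8×10⁻⁴ mm²/s. Choices worth recording:

* **ρ_floor = 1e-5·ρ_peak.** A finite background cellularity keeps the
  relation defined far from the tumour; this value places the map within
  0.1% of the plateau beyond 6σ, and exactly at the plateau where the
  Gaussian underflows to zero (beyond ≈39σ), which the tests assert.
* **Pure scaling, not clipping.** Rescaling preserves the monotonicity
  of D in ρ everywhere; clipping would create a slope-free shelf.
* **Core threshold 0.5.** The simulated core is the cellularity level
  set at half maximum, radius `σ·√(2 ln 2) ≈ 1.18σ`. A higher threshold
  (e.g. 0.9) yields a core radius of 0.46σ — sub-voxel for fronts near
  1 mm on the 0.5 mm grid, which degenerates boundary extraction; half
  maximum keeps every front in the sweep resolvable and matches the
  common FWHM convention for "the visible core".

Sweeping σ over {1, 2, 4, 8} mm with the core as ROI reproduces the
mechanism the biomarker relies on: mean MDS decreases strictly and
steeply with infiltration width (≈1.2e-4 down to ≈3.8e-7 (mm²/s)/mm).
Band ROIs at linearly spaced diffusion thresholds between the core-edge
value and the plateau give nested level sets for sensitivity analyses.

## Synthetic fixtures and what they do (not) show

### Patient phantom

ADC is a function of the signed normal distance `d` from the surface of
an ellipsoidal enhancing core (exact Euclidean distance for the default
spherical core): `adc_core` deep inside, a linear ramp, `adc_plateau`
(8×10⁻⁴ mm²/s) outside, plus optional seeded Gaussian noise. The
segmentation labels the core enhancing and a surrounding shell
(default 7 mm) FLAIR abnormality. The ground truth is
`(adc_plateau − adc_core)/transition_width`.

The default ramp starts 3 mm *inside* the boundary and spans 9 mm. Two
geometric facts force this: profiles are anchored at boundary-voxel
centres, which sit up to one voxel inside the continuous surface; and
the validity rule demands a run longer than 4 mm starting at −2 mm. Only
a ramp covering the entire sampled run makes the linear-fit truth exact.
With a narrower ramp the OLS line mixes ramp with flat segments and
*underestimates* the slope — the documented conservative bias of the
linear fit. The suite quantifies this deliberately: a 4 mm ramp under
the default window recovers ≈0.4 of the nominal ramp slope, and the
pipeline's value agrees with a 1D piecewise-OLS oracle to a few percent.
Recovery tests therefore use the window-spanning ramp (truth exact;
noiseless recovery ≈0.45%, and with noise at 5% of the ADC range the
mean over ≈970 profiles stays within 10%).

A smoothstep (`sigmoid`) profile option exists to study the same bias
against a rounded transition.

### Rodent fixture

Tumour-cell density (TCD) is a solid core with a lobulated outline
(`R(θ) = 1.5 mm·(1 + 0.2·cos 2θ)`) and a Gaussian infiltration skirt
(σ = 0.55 mm); ADC is an affine decreasing function of density
(8×10⁻⁴ → 4×10⁻⁴ mm²/s) plus seeded noise (default 1.2×10⁻⁵ mm²/s, ≈3%
of the dynamic range; the per-profile correlation analyses are also run
at 5% of the range). The lobulated outline matters: a perfectly circular
blob makes each perifocal band an iso-density annulus in which ranks are
driven by noise alone, which no real tumour resembles. The ADC ROI
thresholds the noiseless ADC at the density-0.3 level set and the TCD
footprint at 0.1, both fixed multiples of σ beyond the core surface, so
the infiltration index ROI_TCD/ROI_ADC increases strictly with σ by
construction. Under these conditions voxelwise Spearman correlations in
bands of 4–8 voxels are ≤ −0.85 and the median per-profile Spearman is
≤ −0.93; rodent profiles are analysed over (−1, +2) mm at 4 samples/mm
unless stated, matching the millimetre scale of a mouse tumour margin.

### Survival cohort

Per-patient MDS is normal (mean 2×10⁻⁵, SD 1×10⁻⁵ (mm²/s)/mm); overall
survival is exponential with hazard `λ₀·exp(β·z)` where `z` is the
standardized MDS and `λ₀ = 1/400 days`; age (54 ± 10 y) is independent;
every event is observed (the design follows all subjects to death, so
there is no censoring). `exp(β)` is the true hazard ratio per SD. At
n = 2000 the Cox fit recovers HR 0.5 within ±0.04; Wald 95% CIs cover
the null in ≈93–97% of 200 replicates at n = 100. Coverage is assessed
at β = 0 because with β ≠ 0 the per-replicate sample standardization
rescales the estimand itself (by the ratio of sample to population SD),
which is a property of standardized covariates, not of the Cox
machinery.

What none of the fixtures emulate: Rician noise, EPI distortion,
partial-volume mixtures at the margin, lesion texture, anatomical
barriers (pial/ependymal surfaces) that truncate real profiles, or
registration error between histology and imaging. Passing tests show the
estimator is correct and well-conditioned under the stated geometry and
noise; they do not certify performance on clinical data.

## Statistics

* **Cox model** (lifelines): MDS standardized to zero mean / unit sample
  SD before fitting so the coefficient exponentiates to HR per 1 SD,
  invariant to affine rescaling of the raw values; Efron handling of
  tied death days (ties are certain with day-resolution survival); Wald
  CI and p per term, likelihood-ratio p for the model, Schoenfeld
  residual test for proportional hazards (MDS term).
* **Survival summary**: point estimate is the plain sample median
  (midpoint convention for even n, coinciding with the Kaplan–Meier
  median for odd n — under no censoring KM reduces to the empirical
  survivor function); the CI is the Kaplan–Meier log-log interval.
* **RMCoV** = sd(x₁ᵢ−x₂ᵢ)/mean((x₁ᵢ+x₂ᵢ)/2), with the sample (n−1)
  standard deviation (configurable — the population form is a
  `ddof=0` call away).
* **ICC**: two-way random-effects, absolute-agreement, single-measure
  ICC(2,1) via pingouin, cross-checked in the tests against the
  mean-squares formula; Bland–Altman bias ± 1.96·sd of differences;
  one-way ANOVA for group comparisons. No multiple-testing correction is
  applied anywhere.

## Numerical choices and degenerate inputs

* Out-of-grid space is treated as foreground for boundary extraction, so
  masks clipped by the field of view do not seed normals along the
  clipping plane.
* Interpolation is strictly linear (order 1): exact on affine fields,
  monotonicity-preserving, and free of ringing at the sharp margin.
* Profile samples are assigned to abnormality classes by their
  containing voxel (nearest-centre), not by interpolating labels.
* `n_contiguous_mm` is the arc span `(run length − 1)/rate`, so a run of
  17 samples at 2/mm spans 8 mm.
* Zero valid profiles → NaN patient MDS and a dedicated CLI exit code
  (3); empty ROIs and unknown labels fail loudly with exit code 2.
* Grid equality requires identical shapes and affines within 1e-4 mm.
* Correlation-map caveat: sampling finer than the voxel grid serially
  correlates interpolated samples, inflating |ρ| and invalidating
  nominal p-values under the null; null-calibration checks sample at one
  point per voxel.

## Problem sizes

Defaults were chosen so each validation runs in seconds: 64³ voxels at
1 mm for the patient phantom and sphere phantom (≈1000–2300 surface
vectors), 256² at 0.5 mm for the simulator, 96² at 0.1 mm for the rodent
fixture, n = 2000 (recovery) and 200×100 (coverage) for the survival
simulations. All are configurable; the acceptance script reports the `n`
actually used alongside every value.

## Known limitations

* The normal estimator assumes the surface is locally curve/plane-like
  at the kernel scale; deep concavities narrower than the kernel bias
  normals (the overlap map flags multiply-sampled regions).
* Exact ground-truth slope recovery is guaranteed for spherical cores;
  for ellipsoidal cores the first-order signed distance makes the truth
  approximate at high anisotropy.
* Mean MDS is exactly invariant to axis-permutation rotations and
  integer translations; general rigid rotations incur small
  discretization differences (the sphere-phantom tests bound the
  combined discretization error at a few tenths of a percent).
* Variable-length (adaptive) profile windows and sigmoidal fitting are
  intentionally out of scope.
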