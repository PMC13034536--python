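# mdslope

Quantifying glioblastoma infiltration from diffusion MRI via the
**marginal diffusion slope (MDS)**: the rate of change of the apparent
diffusion coefficient (ADC) along surface-normal profiles crossing the
macroscopic tumour boundary.

Glioblastoma infiltrates the brain well beyond its contrast-enhancing
margin, and conventional structural MRI is largely blind to that
microscopic disease. Because ADC falls with increasing tissue
cellularity, the *spatial gradient* of ADC across the visible tumour
edge carries information about the infiltrative phenotype: a sharp rise
of ADC from tumour to surrounding tissue indicates a well-circumscribed
margin, a shallow rise a diffusely infiltrating one. `mdslope`
implements that biomarker and the validation apparatus around it, for
imaging scientists working with co-registered ADC maps and tumour
segmentations (and, preclinically, with MRI-registered tumour-cell
density maps).

## The metric

Given an enhancing-tumour mask and a co-registered ADC map:

1. **ROI refinement** — morphological closing, hole filling, and
   small-component removal regularize the mask (all foci of multifocal
   disease are retained).
2. **Surface normals** — at every boundary voxel, the boundary points
   inside a centred 5×5(×5) kernel are eigendecomposed in world
   millimetres; the eigenvector of the smallest eigenvalue is the local
   surface normal, oriented outward (centrifugally).
3. **Profile sampling** — ADC is interpolated along each normal over a
   window of −2 mm (inside) to +6 mm (outside) the boundary at
   2 samples/mm.
4. **Validity filter** — a profile counts only where it stays inside the
   combined tumour-abnormality volume (enhancing + non-enhancing core +
   FLAIR abnormality) over a contiguous run containing the boundary
   crossing and spanning strictly more than 4 mm.
5. **Slope fit** — ordinary least squares of ADC against sample index
   over that run, multiplied by the sampling frequency (2 points/mm) to
   give (mm²/s)/mm; the patient-level MDS is the unweighted mean over
   valid profiles.

Supporting modules provide a software sphere phantom, a Gaussian
cellularity→diffusion simulator (Graham's relation, D ∝ 1/√ρ,
normalized to plateau at 8×10⁻⁴ mm²/s), perifocal-band ADC-vs-cellularity
analyses with the infiltration index ROI_TCD/ROI_ADC, survival
statistics (Pearson MDS–OS, Cox proportional hazards with HR per 1 SD of
MDS, Schoenfeld diagnostics), MRI repeatability statistics (RMCoV,
ICC(2,1), Bland–Altman, ANOVA), and synthetic fixtures with built-in
ground truth.

## Worked example

Generate a synthetic patient (spherical enhancing core, surrounding
FLAIR-like shell, marginal ADC ramp with a known slope of
2.222×10⁻⁵ (mm²/s)/mm) and run the pipeline:

```sh
mds fixtures patient --seed 17 --out fx/
mds compute --adc fx/adc.nii.gz --seg fx/seg.nii.gz --out run/
```

which prints

```
mean MDS = 2.21222e-05 (mm^2/s)/mm over 968/968 valid profiles
```

i.e. all 968 surface normals produced valid profiles and the recovered
mean slope is within 0.5% of the imposed truth. `run/` contains the
per-sample profile table, per-vector slopes, a summary JSON, and a
manifest that reproduces the run. The same library calls are available
in Python:

```python
from mdslope import SyntheticPatientSpec, make_synthetic_patient, compute_mds

patient = make_synthetic_patient(SyntheticPatientSpec(seed=17))
result = compute_mds(patient.adc, patient.seg)
print(result.mean_mds, result.n_valid, patient.true_slope)
```

Other subcommands: `mds phantom` (gradient-recovery report on the sphere
phantom), `mds simulate --sigma 1 --sigma 2 --sigma 4` (mean MDS versus
infiltration-front width), `mds preclinical` (band fits + infiltration
index), `mds cohort` (survival statistics from a per-patient CSV).

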