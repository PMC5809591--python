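# ventridisp

Quantifying brain-tumor **mass effect** as lateral ventricle displacement
(LVd): a center-of-mass imaging biomarker, with the survival and
gene-expression analyses it feeds, validated end-to-end on synthetic
phantoms with analytic ground truth.

## The problem and the metric

A growing intracranial tumor displaces the surrounding brain inside the
fixed skull volume. Clinically this *mass effect* is usually eyeballed as
"midline shift", which is operator-dependent and captures only the
left-right direction. LVd replaces it with a reproducible 3-D quantity:

1. Register the subject's T1 image to a reference template with a
   nonlinear diffeomorphic warp `φ(x) = x + u(x)` (template → subject,
   world mm).
2. Carry the template lateral-ventricle (LV) segmentation through the
   warp; exclude voxels of tumor pathology (contrast-enhancing and/or
   FLAIR compartments).
3. Compute the center of mass of the warped, tumor-masked LV mask and of
   the template LV mask, both in template world coordinates:

   `LVd = ‖ COM_subject − COM_template ‖`  (mm),

   with `LVx = |Δx|` (the midline-shift proxy) and the signed displacement
   vector retained for direction-aware analyses.

Because healthy ventricular anatomy varies, a subject's LVd is interpreted
against the LVd distribution of a non-tumor control cohort (mean/SD/range
calibration, "elevated" = exceeds the control maximum).

Downstream, the package provides the standard prognostic and genomic
analyses driven by the metric: median dichotomization, Kaplan-Meier curves
and log-rank tests, Cox proportional-hazards models (Efron ties, Wald CIs)
with age/KPS covariates, and per-gene differential expression between
high/low-LVd groups using Welch t statistics with a label-permutation null
(add-one estimator), within-group bootstrap effect CIs, Benjamini-Hochberg
FDR control, and a local hypergeometric gene-set over-representation test.

## What's in the box

| module | contents |
|---|---|
| `ventridisp.volume_io` | NIfTI I/O, voxel↔world affine contract, displacement fields, fixed-point field inversion, mask warping |
| `ventridisp.phantom` | synthetic head template, diffeomorphic tumor mass-effect phantoms (scaling-and-squaring of a radial velocity) with exact truth, coupled survival cohorts and expression matrices |
| `ventridisp.registration` | multi-resolution demons registration stand-in + external-warp loading |
| `ventridisp.lvd` | center of mass, tumor exclusion, LVd/LVx, control calibration, variance-explained R² |
| `ventridisp.survival` | median split, Kaplan-Meier, log-rank, Cox (lifelines-backed) |
| `ventridisp.diffexpr` | permutation DE scan, BH adjustment, GMT sets, hypergeometric over-representation |
| `ventridisp.cli` | `ventridisp simulate / register / compute / cohort / survival / diffexpr` |

No patient data are required or included: the phantom module generates
everything, with the true displacement known analytically.

## Worked example

```python
import numpy as np
from ventridisp import (PhantomSpec, make_subject, make_template,
                        register, lvd_from_warp)

template, template_lv = make_template()          # 64³ @ 2 mm head phantom
spec = PhantomSpec(tumor_center=(25.0, 10.0, 6.0), tumor_radius=12.0,
                   amplitude=8.0, seed=11, noise_sd=0.02)
subject, tumor_mask, truth = make_subject(spec)

field, diagnostics = register(template, subject, tumor_mask=tumor_mask)
result = lvd_from_warp(template_lv, field, [tumor_mask], subject_id="demo")
print(f"measured LVd = {result.lvd_mm:.2f} mm "
      f"(truth {truth.true_lvd_mm:.2f} mm), LVx = {result.lvx_mm:.2f} mm")
```

prints

```
measured LVd = 1.37 mm (truth 1.93 mm), LVx = 1.14 mm
```

i.e. a right-lateral tumor pushing with 8 mm peak amplitude displaces the
ventricles' center of mass by ~2 mm; the demons registration plus tumor
exclusion recovers that displacement to within ~0.6 mm, and most of it
lies in the left-right axis (the component a midline-shift measurement
would see).

The same flow from a shell:

```sh
ventridisp simulate --n 5 --seed 42 --out run/
ventridisp compute --template-lv run/template_lv.nii.gz \
    --warp run/P0000/truth_field.nii.gz \
    --tumor-mask run/P0000/tumor_mask.nii.gz \
    --subject-id P0000 --out run/P0000.json
ventridisp survival --table run/cohort.csv --outcome os \
    --covariates lvd,age,kps --km-by lvd --out run/fit.json
```

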