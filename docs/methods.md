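# Methods

## Coordinate and field conventions

All geometry lives in world millimetres. Voxel indices are 0-based and
map to world RAS+ coordinates through the NIfTI sform affine (sform
preferred over qform on read; both are written). Displacement fields
store one world-mm 3-vector per voxel of the template grid under the
fixed contract `φ(x) = x + u(x)` mapping template world coordinates to
subject world coordinates; a zero field is the identity. Vector fields
use the 5-D NIfTI layout `[X, Y, Z, 1, 3]` for interoperability with
common registration toolkits, and externally supplied warps must carry a
JSON sidecar declaring `"direction": "template_to_subject"` — a silent
direction flip would negate the metric, so an absent or contradictory
sidecar is an error, not a warning.

Mask warping resamples through the inverse map: the output weight at
voxel `x` is the tri-linearly interpolated input weight at `φ⁻¹(x)`.
Mask/image samples outside the grid read 0; displacement samples outside
the grid extend the edge value, so that e.g. a constant translation field
remains exactly invertible.

### Field inversion

`φ⁻¹` is approximated on the grid by the fixed-point iteration
`v ← v − α (v + u(x + v))` with residual tolerance 0.05 mm. The classic
undamped form (`α = 1`) is only contractive where the local field
gradient `‖∇u‖ < 1`; it oscillates at sharp field transitions and
diverges outright near the core of a strong radial expansion, where the
sampled gradient reaches `‖∇u‖ ≈ A / Δx`. We therefore use a per-point
adaptive damping `α = 1/(1 + L)`, with `L` the finite-difference gradient
magnitude of the field sampled at the current iterate. This is
contractive for any non-folding field; strongly expansive spots simply
need more (heavily damped) sweeps, so points whose residual is below
tolerance are frozen and late sweeps touch only the remaining few. The
sweep cap is 1000; a genuine fold still fails with the max residual
reported.

## The phantom model

The template is a deterministic "head": an ellipsoidal bright skull shell
(semi-axes 50 × 60 × 48 mm) around mid-intensity parenchyma, with two
mirror-symmetric dark ellipsoidal lateral ventricles (centers (±10, −8,
6) mm, semi-axes 6 × 18 × 8 mm). By construction the combined ventricle
center of mass lies exactly on the mid-sagittal plane (x = 0). The
default grid is 64³ at 2 mm isotropic, centered on the head — MNI-like
extents at desk-scale cost; any cubic size/spacing is available through
`make_grid`/`make_template` arguments.

Tumor mass effect is a stationary radial velocity

    v(x) = A · exp(−‖x−c‖² / 2σ²) · (x−c)/(‖x−c‖+ε),   ε = 1e−6 mm,

integrated by scaling-and-squaring (6 squarings) into a diffeomorphism
`φ = exp(v)`; the exact inverse is `exp(−v)`. `A` (mm) sets the peak
push, `σ` (default 25 mm) its reach. Amplitudes are admissible up to
half a voxel times 2⁶ (64 mm at 2 mm spacing), the usual step-size bound
for the scaled composition. The subject image is the template resampled
through `φ⁻¹` with a bright sphere painted at the tumor center and
seeded Gaussian noise (default SD 0.02 on an intensity scale of ~1).

### Ground truth is the *region* centroid

The measurement downstream is the center of mass of the warped ventricle
*region*. The centroid of `φ(LV)` is **not** the plain mean of pushed
particles: under a compressive/expansive map the region centroid weights
each source point by the local volume change `|det Dφ|`. The phantom
truth therefore integrates, along each RK4 trajectory of the analytic
velocity, both the position and the log-Jacobian (`d log J/dt = div v`,
with the divergence in closed form), and defines

    COM_true = Σ J(ξ) φ(ξ) / Σ J(ξ)   over ventricle voxel centers ξ.

The unweighted particle mean differs from the pipeline's measurement by
~0.8 mm already at moderate amplitudes — an intrinsic property of the
metric, not an implementation error — while the Jacobian-weighted truth
agrees with the grid pipeline to ≤ 0.06 mm across the validation suite.
This truth is grid-free (analytic flow), so it is an independent oracle
for the sampled-field pipeline.

For the same reason the metric path (`segment_subject_lv`) warps a
binary ventricle mask with its interpolated fractional weights retained
(probabilistic output) rather than re-binarizing at 0.5: the weighted
COM is then smooth in the deformation, whereas binarized masks move in
discrete voxel jumps (~0.4 mm COM error at sub-voxel displacements).
`warp_mask` itself still re-binarizes binary masks, which is the right
behaviour for segmentation outputs.

## Cohort and expression generators

`make_cohort` samples lateralized tumor geometries (radius 8–15 mm,
center rejection-sampled inside the head and clear of the ventricles),
with push amplitude coupled to radius (`A = r · U(0.3, 3.6)`) so that
LVd correlates positively but imperfectly with tumor volume (r ≈ 0.2;
the residual scatter plays the role of variable tissue compliance). True
LVd is computed by the analytic flow (no image volumes needed), spanning
roughly 0.7–16 mm. CEV is the tumor sphere volume; FHV a dilated-sphere
volume. Survival times are exponential with

    log h = β_LVd·LVd + 0.022·(age−60) − 0.024·(KPS−80)

(age/KPS couplings sized like typical glioblastoma hazard ratios of
~1.02/yr and ~0.98/point), baseline median OS 400 days (PFS 230), with
independent uniform censoring — a proportional-hazards generator, so Cox
recovers `β_LVd` as an identifiable truth. `make_expression` draws
unit-variance Gaussian log-expression with `n_signal` genes shifted by
`effect_size` in the high group.

What the phantoms do **not** emulate: real MR contrast and artifacts,
biomechanically realistic (FEM/poroelastic) tumor growth, infiltrative
FLAIR margins, anatomic variability of ventricles between subjects, and
registration failure modes of heterogeneous clinical data. Passing tests
demonstrate correctness of the computations and recoverability under the
model's assumptions, not clinical performance.

## Registration stand-in

Published pipelines use full toolkits for the diffeomorphic warp; here a
transparent multi-resolution intensity demons serves as a desk-scale
stand-in, with externally computed warps loadable as first-class inputs.
Per pyramid level (default 4 levels, ×2 downsampling with anti-alias
blur) it iterates Thirion forces from the warped-subject gradient,
Gaussian *update* smoothing (fluid-like, σ = 6 mm at finest-grid scale,
applied in level-voxel units so coarse levels smooth proportionally
farther), a per-voxel step cap of half the current level's voxel size,
and certainty-weighted *field* smoothing (elastic-like, σ = 1 mm) using
template signal support as the certainty — plain smoothing lets the
empty background drag the field to zero through thin head regions, which
is why a global 4 mm translation would otherwise under-recover. An
update is accepted only if the tumor-masked MSE decreases (backtracking
halves the step otherwise), so the recorded MSE trajectory is monotone;
with fixed processing order the result is bit-reproducible.

The optimizer warps the *subject* toward the template (`T(x) ≈ S(φ(x))`
at matched tissue), so its variable is directly the forward field the
package stores — no lossy output-side inversion. Voxels inside the
2-voxel-dilated tumor mask, tracked through the current warp, are
excluded from both force and error: tumor tissue has no template
correspondence and would otherwise corrupt the field near the
ventricles.

On the 20-phantom validation suite (amplitudes 1–10 mm, noise SD 0.02)
the defaults recover LVd with median error ≈ 0.2 mm and worst case
≤ 0.8 mm; accuracy was tuned on phantom ground truth, since no published
hyper-parameters exist to match.

## Statistics

* **Median split**: high iff value > median (ties to the low group),
  median of the complete cases of the model at hand.
* **KM/log-rank/Cox** delegate to lifelines: product-limit estimator
  (median = earliest time with Ŝ ≤ 0.5, undefined if never reached),
  two-group log-rank with 1-df χ², Cox partial likelihood with the Efron
  ties correction and Wald CIs/p-values. Complete-case analysis per
  model with the used n reported. Tests cross-check against a
  hand-coded Efron log-likelihood maximized by 1-D grid search. Only
  Efron ties handling is exposed.
* **Permutation DE**: Welch t per gene; the whole label vector is
  shuffled once per cycle for all genes (preserving gene–gene
  correlation); `p = (1 + #{|t*| ≥ |t|}) / (1 + n_perm)` (add-one, never
  zero). A 1e-9 relative tolerance on the exceedance comparison keeps
  exact ties counted across the two numerical routes (per-gene vs
  blocked matmul). Bootstrap (within-group, with replacement) yields
  percentile 95% CIs of the mean-difference effect — the bootstrap's
  role is interval estimation, not significance. Genes with zero
  variance in both groups get statistic 0, p 1, and a `zero_variance`
  flag.
* **BH**: step-up `q_(j) = min_{k≥j} m·p_(k)/k` capped at 1 (via
  statsmodels), asserted against the hand formula.
* **Over-representation**: one-sided hypergeometric tail per gene set
  restricted to the analysis universe, BH across sets — a local,
  dependency-free replacement for web-service ontology tools; it tests
  membership enrichment only, not ontology-aware propagation.

## Numerical choices and degenerate inputs

Tri-linear interpolation throughout (deterministic, smooth,
conservative); re-binarization threshold 0.5 where binary output is
required. Empty masks, non-finite voxels (reported with counts),
singular affines, mismatched grids, degenerate median splits, and
out-of-range p-values raise typed errors (`DataError` vs
`ConvergenceError`; CLI exit codes 3 and 4). Control calibration with
zero SD yields a NaN z-score with the classification still defined.
Classification boundary: a value equal to the control maximum counts as
within the control range ("elevated" means strictly exceeding it).

## Validation problem sizes

The shipped validation (`scripts/acceptance.py`, ~5 min on one CPU) uses
20 phantoms at 64³/2 mm for metric and registration recovery; n = 500
cohorts (one recovery, 50 null replicates) for Cox; 2000 genes × 40
samples with 2000 permutations for calibration (type-I error, and
realized FDR over 20 replicates of a 10%-signal, 1.5-SD-effect design);
and 72³/1 mm grids for inverse-warp Dice. These sizes give tight Monte
Carlo error while staying desk-scale; all generators accept larger
sizes.

## Known limitations

* The demons stand-in assumes intensity-comparable images on a shared
  grid (no affine pre-alignment, no cross-modality metric).
* One combined LV mask (single COM); no left/right decomposition, no
  ventricle volume-change analysis.
* The permutation null assumes exchangeability of samples under the
  label split; confounded designs are not detected.
* Probe-to-gene collapsing and count-based RNA-seq modeling are out of
  scope; inputs are assumed to be processed log-scale matrices.
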