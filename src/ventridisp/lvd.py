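"""Lateral ventricle displacement (LVd): the core biomarker computation.

The metric quantifies tumor mass effect as the displacement of the lateral
ventricles' center of mass.  A template ventricle mask is carried into the
subject by the nonlinear warp, voxels of tumor pathology are excluded, and
the Euclidean distance (mm, template world space) between the resulting
center of mass and the template ventricle center of mass is the LVd.  The
absolute x (left-right) component, LVx, is a computational proxy for
clinical midline shift; it captures only one of the three cardinal
directions of mass effect.

Because ventricle anatomy varies between healthy individuals, a nonzero
LVd is expected even without a tumor; a subject's value is interpreted
against a control distribution via :func:`calibrate_controls` and
:func:`classify`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .errors import DataError
from .volume_io import DisplacementField, LabelVolume, voxel_to_world, warp_mask

__all__ = [
    "LVdResult",
    "ControlCalibration",
    "center_of_mass",
    "segment_subject_lv",
    "compute_lvd",
    "lvd_from_warp",
    "calibrate_controls",
    "classify",
    "variance_explained",
]

#: warped-ventricle fraction removed by tumor masking that triggers a QC flag
HEAVY_OVERLAP_FRACTION = 0.5


@dataclass(frozen=True)
class LVdResult:
    """Displacement of the ventricle center of mass, with components.

    ``displacement`` keeps the signed vector (subject COM - template COM,
    world mm) for direction-aware analyses; ``lvx_mm``/``lvy_mm``/
    ``lvz_mm`` are its absolute axis components.
    """

    subject_id: str
    com_template: np.ndarray
    com_subject: np.ndarray
    displacement: np.ndarray
    lvd_mm: float
    lvx_mm: float
    lvy_mm: float
    lvz_mm: float
    excluded_voxel_fraction: float = 0.0
    qc_flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "com_template": list(map(float, self.com_template)),
            "com_subject": list(map(float, self.com_subject)),
            "displacement": list(map(float, self.displacement)),
            "lvd_mm": self.lvd_mm,
            "lvx_mm": self.lvx_mm,
            "lvy_mm": self.lvy_mm,
            "lvz_mm": self.lvz_mm,
            "excluded_voxel_fraction": self.excluded_voxel_fraction,
            "qc_flags": list(self.qc_flags),
        }


@dataclass(frozen=True)
class ControlCalibration:
    """Summary of the LVd distribution in a non-tumor control cohort."""

    n_controls: int
    mean_mm: float
    sd_mm: float
    min_mm: float
    max_mm: float


def center_of_mass(mask: LabelVolume) -> np.ndarray:
    """Weight-weighted mean of voxel-center world coordinates (mm).

    Probabilistic weights are used as-is; binary masks give the unweighted
    centroid of their voxels.
    """
    w = mask.weights
    total = w.sum()
    if total <= 0:
        raise DataError("center of mass of an empty mask is undefined")
    nz = np.argwhere(w > 0)
    pts = voxel_to_world(mask.grid, nz.astype(float))
    return (w[tuple(nz.T)][:, None] * pts).sum(axis=0) / total


def segment_subject_lv(
    template_lv: LabelVolume,
    fld: DisplacementField,
    tumor_masks: list[LabelVolume] | None = None,
) -> tuple[LabelVolume, float, tuple[str, ...]]:
    """Subject ventricle segmentation: warp, then exclude tumor voxels.

    The template ventricle mask is carried through the warp; any voxel
    belonging to the union of the supplied tumor compartments (e.g.
    contrast-enhancing and FLAIR) is then zeroed.  Returns the mask, the
    fraction of warped ventricle weight removed by the exclusion, and QC
    flags (``heavy_tumor_overlap`` when more than half is removed).

    A binary template mask is warped with its interpolated fractional
    weights retained (probabilistic output): the subsequent center of mass
    is then smooth in the deformation, whereas re-binarization would
    quantize sub-voxel displacements to discrete COM jumps.
    """
    if template_lv.kind == "binary":
        template_lv = LabelVolume(grid=template_lv.grid,
                                  weights=template_lv.weights,
                                  kind="probabilistic")
    warped = warp_mask(template_lv, fld)
    if not tumor_masks:
        return warped, 0.0, ()

    union = np.zeros(warped.grid.shape, dtype=bool)
    for tm in tumor_masks:
        if not tm.grid.same_geometry(warped.grid):
            raise DataError("tumor mask grid does not match the template grid")
        union |= tm.weights > 0.5

    before = warped.weights.sum()
    weights = np.where(union, 0.0, warped.weights)
    after = weights.sum()
    if after == 0:
        raise DataError("LV fully engulfed: tumor exclusion removed the whole mask")
    excluded = float((before - after) / before)
    flags = ("heavy_tumor_overlap",) if excluded > HEAVY_OVERLAP_FRACTION else ()
    return (
        LabelVolume(grid=warped.grid, weights=weights, kind=warped.kind),
        excluded,
        flags,
    )


def compute_lvd(
    template_lv: LabelVolume,
    subject_lv: LabelVolume,
    subject_id: str = "",
    excluded_voxel_fraction: float = 0.0,
    qc_flags: tuple[str, ...] = (),
) -> LVdResult:
    """LVd between a template and a subject ventricle mask (same world frame)."""
    com_t = center_of_mass(template_lv)
    com_s = center_of_mass(subject_lv)
    disp = com_s - com_t
    return LVdResult(
        subject_id=subject_id,
        com_template=com_t,
        com_subject=com_s,
        displacement=disp,
        lvd_mm=float(np.linalg.norm(disp)),
        lvx_mm=float(abs(disp[0])),
        lvy_mm=float(abs(disp[1])),
        lvz_mm=float(abs(disp[2])),
        excluded_voxel_fraction=excluded_voxel_fraction,
        qc_flags=qc_flags,
    )


def lvd_from_warp(
    template_lv: LabelVolume,
    fld: DisplacementField,
    tumor_masks: list[LabelVolume] | None = None,
    subject_id: str = "",
) -> LVdResult:
    """Full metric pipeline: warp the template ventricles, exclude tumor,
    measure the center-of-mass displacement."""
    subject_lv, excluded, flags = segment_subject_lv(template_lv, fld, tumor_masks)
    return compute_lvd(template_lv, subject_lv, subject_id=subject_id,
                       excluded_voxel_fraction=excluded, qc_flags=flags)


def calibrate_controls(control_lvds) -> ControlCalibration:
    """Summarize a control (non-tumor) LVd sample."""
    vals = np.asarray(list(control_lvds), dtype=float)
    if vals.size < 2:
        raise DataError("control calibration needs at least 2 values")
    return ControlCalibration(
        n_controls=int(vals.size),
        mean_mm=float(vals.mean()),
        sd_mm=float(vals.std(ddof=1)),
        min_mm=float(vals.min()),
        max_mm=float(vals.max()),
    )


def classify(lvd_mm: float, calib: ControlCalibration) -> tuple[str, float]:
    """Classify an LVd value against the control range.

    ``elevated`` means strictly exceeding the control maximum (a value
    equal to the maximum counts as within range).  The z-score is relative
    to the control mean/SD; NaN (with no exception) when the control SD is
    zero.
    """
    label = "elevated" if lvd_mm > calib.max_mm else "within_control_range"
    z = (lvd_mm - calib.mean_mm) / calib.sd_mm if calib.sd_mm > 0 else float("nan")
    return label, float(z)


def variance_explained(lvd, predictors) -> float:
    """OLS coefficient of determination of LVd on tumor-volume predictors.

    ``predictors`` is an (n,) or (n, k) array (e.g. CEV, or CEV and FHV
    columns, mm^3).  Used to quantify how much of the displacement variance
    plain tumor bulk accounts for.
    """
    y = np.asarray(lvd, dtype=float)
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if y.shape[0] != X.shape[0]:
        raise DataError("response and predictors have different lengths")
    if y.shape[0] <= X.shape[1] + 1:
        raise DataError("too few observations for the number of predictors")
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), X])) < X.shape[1] + 1:
        raise DataError("degenerate design matrix")
    model = sm.OLS(y, sm.add_constant(X)).fit()
    return float(model.rsquared)
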