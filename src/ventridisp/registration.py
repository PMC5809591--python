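"""Desk-scale nonlinear registration: multi-resolution demons.

Estimates the template-to-subject displacement field when no externally
computed warp is supplied.  The optimizer is a classic intensity demons:
at each pyramid level it iterates

1. warp the template through the current (inverse-direction) field,
2. compute Thirion demons forces from the intensity mismatch and the
   warped-template gradient,
3. smooth the update (fluid-like) and the accumulated field
   (elastic-like), with a per-voxel step-length cap,

accepting an update only if the masked mean-squared intensity error
decreases (with step backtracking otherwise), so the recorded MSE
trajectory is monotone.  Voxels inside the (dilated) tumor mask are
excluded from both the force and the error: the tumor has no template
correspondence, and letting it pull on the field would corrupt the
ventricle displacement estimate.

The optimizer warps the *subject* toward the template, so its variable is
directly the forward map ``phi = id + u`` of the package's
template-to-subject convention (``T(x) = S(phi(x))`` at matched tissue):
no field inversion is needed on output.  Fixed processing order and no
data-dependent randomness make the result bit-reproducible for a given
configuration.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter, zoom

from .errors import ConvergenceError, DataError
from .volume_io import (
    DisplacementField,
    LabelVolume,
    ScalarVolume,
    VolumeGrid,
    read_field,
    sample_volume_world,
)

__all__ = ["RegistrationConfig", "register", "load_external_field"]


@dataclass(frozen=True)
class RegistrationConfig:
    """Demons hyper-parameters.

    ``step_cap_mm = None`` means half the (finest-level) voxel size.
    ``convergence_tol`` is the relative MSE improvement below which a level
    stops.
    """

    pyramid_levels: int = 4
    iterations_per_level: int = 100
    update_smoothing_sigma_mm: float = 6.0
    field_smoothing_sigma_mm: float = 1.0
    step_cap_mm: float | None = None
    convergence_tol: float = 1e-4
    max_backtracks: int = 6

    def __post_init__(self):
        if self.pyramid_levels < 1 or self.iterations_per_level < 1:
            raise DataError("levels and iterations must be >= 1")
        for name in ("update_smoothing_sigma_mm", "field_smoothing_sigma_mm",
                     "convergence_tol"):
            if getattr(self, name) <= 0:
                raise DataError(f"{name} must be > 0")


def _downsample_grid(grid: VolumeGrid, factor: int) -> VolumeGrid:
    affine = grid.affine.copy()
    affine[:3, :3] *= factor
    shape = tuple(max(1, s // factor) for s in grid.shape)
    return VolumeGrid(shape=shape, affine=affine, space_label=grid.space_label)


def _downsample_values(values: np.ndarray, factor: int,
                       shape: tuple[int, ...]) -> np.ndarray:
    if factor == 1:
        return values.astype(float)
    sm = gaussian_filter(values.astype(float), sigma=factor / 2.0)
    out = zoom(sm, [t / s for t, s in zip(shape, values.shape)], order=1)
    return out


def _world_gradient(values: np.ndarray, affine: np.ndarray) -> np.ndarray:
    g_vox = np.stack(np.gradient(values), axis=-1)
    return g_vox @ np.linalg.inv(affine[:3, :3])


def register(
    template: ScalarVolume,
    subject: ScalarVolume,
    cfg: RegistrationConfig = RegistrationConfig(),
    tumor_mask: LabelVolume | None = None,
) -> tuple[DisplacementField, dict]:
    """Estimate the template-to-subject displacement field.

    Returns the field (``phi - id``, world mm on the template grid) and a
    diagnostics dict with per-level MSE trajectories and iteration counts.

    Raises :class:`DataError` on mismatched grids and
    :class:`ConvergenceError` if the mismatch grows for 10 consecutive
    candidate steps even after backtracking.
    """
    if not template.grid.same_geometry(subject.grid):
        raise DataError("template and subject must share a grid")
    grid = template.grid

    exclude_full = None
    if tumor_mask is not None:
        if not tumor_mask.grid.same_geometry(grid):
            raise DataError("tumor mask grid does not match the image grid")
        exclude_full = binary_dilation(tumor_mask.weights > 0.5, iterations=2)

    factors = [2 ** (cfg.pyramid_levels - 1 - lv) for lv in range(cfg.pyramid_levels)]
    diagnostics = {"levels": []}
    w = None  # phi - id on the current level grid

    for factor in factors:
        lgrid = _downsample_grid(grid, factor)
        t_vals = _downsample_values(template.values, factor, lgrid.shape)
        s_vals = _downsample_values(subject.values, factor, lgrid.shape)
        excl_vals = None
        if exclude_full is not None:
            excl_vals = _downsample_values(exclude_full.astype(float), factor,
                                           lgrid.shape)

        x_world = lgrid.voxel_centers_world()
        spacing = lgrid.spacing
        # sigmas are specified in finest-grid mm but applied in level-voxel
        # units, so coarse levels smooth over proportionally larger mm
        # distances (the classic pyramid behaviour that lets deformation
        # diffuse through featureless regions)
        sig_up_vox = cfg.update_smoothing_sigma_mm / grid.spacing
        sig_field_vox = cfg.field_smoothing_sigma_mm / grid.spacing
        # cap steps at half a voxel of the *current* level, so coarse levels
        # can traverse large displacements in few iterations
        step_cap = cfg.step_cap_mm * factor if cfg.step_cap_mm is not None \
            else 0.5 * float(np.min(spacing))
        kappa = float(np.mean(spacing))

        if w is None:
            w = np.zeros(lgrid.shape + (3,))
        else:
            w = np.stack(
                [zoom(w[..., c], [t / s for t, s in zip(lgrid.shape, w.shape[:3])],
                      order=1) for c in range(3)], axis=-1)

        def warp_mse(w_arr):
            pts = x_world + w_arr
            warped = sample_volume_world(s_vals, lgrid, pts)
            diff = warped - t_vals
            include = np.ones(lgrid.shape, dtype=bool)
            if excl_vals is not None:
                # tumor voxels, tracked through the current warp
                include = sample_volume_world(excl_vals, lgrid, pts) < 0.25
            diff[~include] = 0.0
            return warped, diff, float(np.mean(diff[include] ** 2))

        # certainty for normalized field smoothing: voxels with template
        # signal support; keeps the empty background from dragging the
        # field toward zero through thin parts of the head
        support = (t_vals > 0.1 * np.percentile(t_vals, 95)).astype(float)
        support_sm = [gaussian_filter(support, sigma=sig_field_vox)]

        def smooth_field(arr):
            out = np.empty_like(arr)
            denom = np.maximum(support_sm[0], 1e-3)
            for c in range(3):
                out[..., c] = gaussian_filter(arr[..., c] * support,
                                              sigma=sig_field_vox) / denom
            return out

        warped, diff, mse = warp_mse(w)
        mse_history = [mse]
        step_scale = 1.0
        n_accepted = 0
        stalled = 0
        consecutive_bad = 0

        for _ in range(cfg.iterations_per_level):
            grad = _world_gradient(warped, lgrid.affine)
            gnorm2 = np.sum(grad ** 2, axis=-1)
            denom = gnorm2 + (diff ** 2) / (kappa ** 2)
            scale = np.where(denom > 1e-9, -diff / np.maximum(denom, 1e-9), 0.0)
            delta = scale[..., None] * grad
            for c in range(3):
                delta[..., c] = gaussian_filter(delta[..., c], sigma=sig_up_vox)
            # per-voxel step cap
            dnorm = np.linalg.norm(delta, axis=-1, keepdims=True)
            cap = step_cap * step_scale
            delta *= np.minimum(1.0, cap / np.maximum(dnorm, 1e-12))

            w_cand = smooth_field(w + delta)
            warped_c, diff_c, mse_c = warp_mse(w_cand)

            if mse_c <= mse:
                improvement = (mse - mse_c) / max(mse, 1e-30)
                w, warped, diff, mse = w_cand, warped_c, diff_c, mse_c
                mse_history.append(mse)
                n_accepted += 1
                step_scale = min(1.0, step_scale * 2.0)
                consecutive_bad = 0
                stalled = stalled + 1 if improvement < cfg.convergence_tol else 0
                if stalled >= 3:
                    break
            else:
                consecutive_bad += 1
                if consecutive_bad >= 10:
                    raise ConvergenceError(
                        "registration diverged: MSE increased for 10 "
                        f"consecutive candidate steps (MSE {mse:.6g} -> {mse_c:.6g})"
                    )
                step_scale *= 0.5
                if step_scale < 2.0 ** -cfg.max_backtracks:
                    break

        diagnostics["levels"].append({
            "factor": factor,
            "shape": lgrid.shape,
            "mse": mse_history,
            "final_mse": mse,
            "iterations_accepted": n_accepted,
        })

    return DisplacementField(grid=grid, vectors=w), diagnostics


def _sidecar_path(path: str) -> str:
    base = str(path)
    for suffix in (".nii.gz", ".nii"):
        if base.endswith(suffix):
            return base[: -len(suffix)] + ".json"
    return base + ".json"


def load_external_field(
    path: str | os.PathLike, expected_grid: VolumeGrid | None = None
) -> DisplacementField:
    """Load an externally computed warp with its direction sidecar.

    The NIfTI field must be accompanied by ``<stem>.json`` declaring
    ``{"direction": "template_to_subject"}``; anything else is rejected so
    a field with the opposite convention cannot silently flip the metric.
    """
    fld = read_field(path)
    sidecar = _sidecar_path(str(path))
    if not os.path.exists(sidecar):
        raise DataError(f"missing direction sidecar {sidecar}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    direction = meta.get("direction")
    if direction != "template_to_subject":
        raise DataError(
            f"sidecar {sidecar}: direction {direction!r} contradicts the "
            "required template_to_subject contract"
        )
    if expected_grid is not None and not fld.grid.same_geometry(expected_grid):
        raise DataError("external field grid does not match the expected grid")
    return fld
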