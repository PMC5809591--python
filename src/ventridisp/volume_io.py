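"""NIfTI volume and displacement-field I/O, coordinates, and mask warping.

This module owns the voxel/world coordinate contract used everywhere else:

* voxel indices are 0-based;
* world coordinates are RAS+ millimetres, given by the sform affine
  (``world = A @ [i, j, k, 1]``);
* displacement fields store one 3-vector per voxel, in world-axis mm,
  with the fixed direction convention ``phi(x) = x + u(x)`` mapping
  *template* world coordinates to *subject* world coordinates.

Because stored fields are forward maps, resampling a template mask into
subject space goes through the inverse ``phi**-1``, which is approximated
by fixed-point iteration (see :func:`invert_field`).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Literal

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

from .errors import ConvergenceError, DataError

__all__ = [
    "VolumeGrid",
    "ScalarVolume",
    "LabelVolume",
    "DisplacementField",
    "read_volume",
    "write_volume",
    "read_field",
    "write_field",
    "voxel_to_world",
    "world_to_voxel",
    "sample_volume_world",
    "sample_field_world",
    "compose_fields",
    "invert_field",
    "warp_mask",
]

#: residual tolerance (mm) for fixed-point inversion of a displacement field
INVERT_TOL_MM = 0.05
#: sweep cap for fixed-point inversion; strongly expansive spots need many
#: heavily damped sweeps, but converged points are frozen so sweeps are cheap
INVERT_MAX_ITER = 1000


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VolumeGrid:
    """A sampling grid: voxel array shape plus a voxel-to-world affine.

    Parameters
    ----------
    shape
        Number of voxels along each of the three axes.
    affine
        4x4 matrix mapping homogeneous 0-based voxel indices to world mm
        (RAS+ orientation by convention).
    space_label
        Free-text tag for the coordinate frame, e.g. ``"template"``.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray
    space_label: str = ""

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise DataError(f"grid shape must be 3 positive integers, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise DataError(f"affine must be 4x4, got shape {affine.shape}")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise DataError("affine upper-left 3x3 block is singular")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm along each voxel axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_centers_world(self) -> np.ndarray:
        """World coordinates of every voxel center, shape ``self.shape + (3,)``."""
        idx = np.stack(
            np.meshgrid(*(np.arange(s) for s in self.shape), indexing="ij"), axis=-1
        ).astype(float)
        return voxel_to_world(self, idx)

    def same_geometry(self, other: "VolumeGrid", tol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=tol
        )


@dataclass(frozen=True)
class ScalarVolume:
    """A scalar image on a grid (e.g. a T1-like intensity volume)."""

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.grid.shape:
            raise DataError(
                f"values shape {values.shape} != grid shape {self.grid.shape}"
            )
        n_bad = int(np.size(values) - np.isfinite(values).sum())
        if n_bad:
            raise DataError(f"volume contains {n_bad} non-finite voxels")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class LabelVolume:
    """A mask on a grid: binary {0,1} or probabilistic weights in [0,1]."""

    grid: VolumeGrid
    weights: np.ndarray
    kind: Literal["binary", "probabilistic"] = "binary"

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != self.grid.shape:
            raise DataError(f"weights shape {w.shape} != grid shape {self.grid.shape}")
        n_bad = int(np.size(w) - np.isfinite(w).sum())
        if n_bad:
            raise DataError(f"mask contains {n_bad} non-finite voxels")
        if self.kind == "binary":
            if not np.all((w == 0) | (w == 1)):
                raise DataError("binary mask has weights outside {0, 1}")
        elif self.kind == "probabilistic":
            if w.min() < 0 or w.max() > 1:
                raise DataError("probabilistic mask has weights outside [0, 1]")
        else:
            raise DataError(f"unknown mask kind {self.kind!r}")
        object.__setattr__(self, "weights", w)

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())


@dataclass(frozen=True)
class DisplacementField:
    """Per-voxel world-mm displacement ``u`` with ``phi(x) = x + u(x)``.

    The grid lives in the template frame; ``phi`` maps template world
    coordinates to subject world coordinates.  A field of zeros is the
    identity map.
    """

    grid: VolumeGrid
    vectors: np.ndarray
    direction: str = field(default="template_to_subject")

    def __post_init__(self):
        v = np.asarray(self.vectors, dtype=float)
        if v.shape != self.grid.shape + (3,):
            raise DataError(
                f"vectors shape {v.shape} != grid shape + (3,) {self.grid.shape + (3,)}"
            )
        n_bad = int(np.size(v) - np.isfinite(v).sum())
        if n_bad:
            raise DataError(f"field contains {n_bad} non-finite components")
        object.__setattr__(self, "vectors", v)


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------

def voxel_to_world(grid: VolumeGrid, index: np.ndarray) -> np.ndarray:
    """Map (continuous) 0-based voxel indices to world mm.

    ``index`` may be a single triple or any ``(..., 3)`` array.
    """
    idx = np.asarray(index, dtype=float)
    return idx @ grid.affine[:3, :3].T + grid.affine[:3, 3]


def world_to_voxel(grid: VolumeGrid, point: np.ndarray) -> np.ndarray:
    """Map world-mm points to continuous 0-based voxel indices (inverse of
    :func:`voxel_to_world`)."""
    pts = np.asarray(point, dtype=float)
    inv = np.linalg.inv(grid.affine)
    return pts @ inv[:3, :3].T + inv[:3, 3]


def sample_volume_world(
    values: np.ndarray,
    grid: VolumeGrid,
    world_pts: np.ndarray,
    order: int = 1,
    mode: str = "constant",
) -> np.ndarray:
    """Tri-linearly sample a voxel array at world-mm points.

    With the default ``mode="constant"``, samples outside the grid read 0
    (the convention for mask weights and images).
    """
    vox = world_to_voxel(grid, world_pts)
    flat = vox.reshape(-1, 3).T
    out = map_coordinates(
        np.asarray(values, dtype=float), flat, order=order, mode=mode, cval=0.0
    )
    return out.reshape(world_pts.shape[:-1])


def sample_field_world(fld: DisplacementField, world_pts: np.ndarray) -> np.ndarray:
    """Sample the displacement vectors at world points.

    Componentwise tri-linear; outside the grid the edge value is extended,
    so e.g. a constant translation field remains exactly invertible.
    """
    out = np.empty(world_pts.shape)
    for c in range(3):
        out[..., c] = sample_volume_world(
            fld.vectors[..., c], fld.grid, world_pts, mode="nearest"
        )
    return out


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _affine_from_header(img) -> np.ndarray:
    """sform preferred over qform, per the package's NIfTI dialect."""
    hdr = img.header
    sform, scode = hdr.get_sform(coded=True)
    if scode != 0:
        return np.asarray(sform, dtype=float)
    qform, qcode = hdr.get_qform(coded=True)
    if qcode != 0:
        return np.asarray(qform, dtype=float)
    return np.asarray(img.affine, dtype=float)


def read_volume(
    path: str | os.PathLike,
    as_label: Literal["binary", "probabilistic"] | None = None,
) -> ScalarVolume | LabelVolume:
    """Read a 3-D NIfTI-1 volume (optionally gzipped).

    If ``as_label`` is given the data are validated and returned as a
    :class:`LabelVolume` of that kind; otherwise a :class:`ScalarVolume`.
    """
    if not os.path.exists(path):
        raise DataError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DataError(f"{path}: expected a 3-D image, got {data.ndim}-D")
    grid = VolumeGrid(shape=data.shape, affine=_affine_from_header(img))
    if as_label is not None:
        return LabelVolume(grid=grid, weights=data, kind=as_label)
    return ScalarVolume(grid=grid, values=data)


def write_volume(vol: ScalarVolume | LabelVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1 with the grid affine as sform (and qform).

    Binary masks are stored with an integer datatype so they re-read
    bit-exactly.
    """
    if isinstance(vol, LabelVolume):
        data = vol.weights
        if vol.kind == "binary":
            data = data.astype(np.uint8)
    else:
        data = vol.values
    img = nib.Nifti1Image(np.asarray(data), vol.grid.affine)
    img.header.set_sform(vol.grid.affine, code=2)
    img.header.set_qform(vol.grid.affine, code=2)
    nib.save(img, str(path))


def read_field(path: str | os.PathLike) -> DisplacementField:
    """Read a displacement field stored as a 5-D NIfTI with dim [X,Y,Z,1,3].

    Components are world-axis mm; the template-to-subject direction contract
    is attached on read.
    """
    if not os.path.exists(path):
        raise DataError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[-1] == 3:
        raise DataError(
            f"{path}: got dim [X,Y,Z,3]; vector fields must use the 5-D "
            "NIfTI convention [X,Y,Z,1,3]"
        )
    if data.ndim != 5 or data.shape[3] != 1 or data.shape[4] != 3:
        raise DataError(
            f"{path}: expected vector-field dims [X,Y,Z,1,3], got {data.shape}"
        )
    grid = VolumeGrid(shape=data.shape[:3], affine=_affine_from_header(img))
    return DisplacementField(grid=grid, vectors=data[:, :, :, 0, :])


def write_field(fld: DisplacementField, path: str | os.PathLike) -> None:
    """Write a displacement field using the [X,Y,Z,1,3] NIfTI convention."""
    data = fld.vectors[:, :, :, np.newaxis, :]
    img = nib.Nifti1Image(data, fld.grid.affine)
    img.header.set_sform(fld.grid.affine, code=2)
    img.header.set_qform(fld.grid.affine, code=2)
    img.header.set_intent("vector")
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# field algebra and warping
# ---------------------------------------------------------------------------

def compose_fields(
    outer: DisplacementField, inner: DisplacementField
) -> DisplacementField:
    """Displacement of the composition ``phi_outer o phi_inner``.

    ``u(x) = u_inner(x) + u_outer(x + u_inner(x))``, sampled on the inner
    field's grid.
    """
    if not outer.grid.same_geometry(inner.grid):
        raise DataError("cannot compose fields on different grids")
    x = inner.grid.voxel_centers_world()
    u = inner.vectors + sample_field_world(outer, x + inner.vectors)
    return replace(inner, vectors=u)


def _field_lipschitz(fld: DisplacementField) -> np.ndarray:
    """Per-voxel bound on the local gradient magnitude of the field
    (Frobenius norm of the finite-difference Jacobian of u in world mm)."""
    inv_lin = np.linalg.inv(fld.grid.affine[:3, :3])
    total = np.zeros(fld.grid.shape)
    for c in range(3):
        g_vox = np.stack(np.gradient(fld.vectors[..., c]), axis=-1)
        g_world = g_vox @ inv_lin
        total += np.sum(g_world ** 2, axis=-1)
    return np.sqrt(total)


def invert_field(
    fld: DisplacementField,
    max_iter: int = INVERT_MAX_ITER,
    tol_mm: float = INVERT_TOL_MM,
) -> DisplacementField:
    """Approximate the displacement of ``phi**-1`` on the same grid.

    Fixed-point iteration ``v <- v - alpha * (v + u(x + v))`` with a
    per-point adaptive damping ``alpha = 1 / (1 + L)``, where ``L`` is the
    local gradient magnitude of ``u`` at the current sample position.  The
    undamped map (``alpha = 1``) diverges wherever the field's local
    gradient exceeds 1 -- e.g. close to the center of a strong radial
    expansion -- while the adaptive damping stays contractive for any
    non-folding field, at the cost of more sweeps there.  Points whose
    residual ``||v + u(x + v)||`` is already below ``tol_mm`` are frozen,
    so late sweeps touch only the few stubborn points.  Raises
    :class:`ConvergenceError` with the max residual if the cap is hit.
    """
    x = fld.grid.voxel_centers_world().reshape(-1, 3)
    v = np.zeros_like(x)
    lips = _field_lipschitz(fld)

    active = np.arange(x.shape[0])
    residual = np.inf
    for _ in range(max_iter):
        pts = x[active] + v[active]
        u_at = sample_field_world(fld, pts)
        res_vec = v[active] + u_at
        res = np.linalg.norm(res_vec, axis=-1)
        residual = float(res.max()) if res.size else 0.0
        if residual < tol_mm:
            break
        l_at = sample_volume_world(lips, fld.grid, pts, mode="nearest")
        alpha = 1.0 / (1.0 + np.maximum(l_at, 0.0))
        v[active] -= alpha[:, None] * res_vec
        keep = res >= 0.5 * tol_mm
        active = active[keep]
    else:
        raise ConvergenceError(
            f"field inversion did not converge in {max_iter} iterations "
            f"(max residual {residual:.3f} mm > {tol_mm} mm)"
        )
    return replace(fld, vectors=v.reshape(fld.grid.shape + (3,)))


def warp_mask(mask: LabelVolume, fld: DisplacementField) -> LabelVolume:
    """Image of a template-space mask under ``phi``, sampled on the same grid.

    Output weight at voxel ``x`` is the tri-linearly interpolated input
    weight at ``phi**-1(x)``; binary masks are re-binarized at 0.5.
    """
    if not mask.grid.same_geometry(fld.grid):
        raise DataError("mask and field must share a grid")
    inv = invert_field(fld)
    x = mask.grid.voxel_centers_world()
    w = sample_volume_world(mask.weights, mask.grid, x + inv.vectors)
    w = np.clip(w, 0.0, 1.0)
    if mask.kind == "binary":
        w = (w >= 0.5).astype(float)
    if w.sum() == 0:
        raise DataError("warped mask is empty")
    return LabelVolume(grid=mask.grid, weights=w, kind=mask.kind)
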