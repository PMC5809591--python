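"""Synthetic mass-effect phantoms with analytic ground truth.

A phantom "head" is a smooth ellipsoidal skull/parenchyma image with two
mirror-symmetric dark lateral ventricles, standing in for a symmetric
reference template.  A tumor is modelled as a bright sphere whose growth
pushes surrounding tissue outward along radial lines, with Gaussian decay
of the push with distance.  The outward push is encoded as a stationary
velocity field and integrated by scaling-and-squaring, so the resulting
deformation ``phi`` is diffeomorphic (invertible) for any amplitude below
the step-size bound, and its exact inverse is the integral of the negated
velocity.

Every phantom carries its ground truth: the sampled displacement field
``phi - id``, the true displaced ventricle center of mass (push-forward of
the template ventricle voxel centers through ``phi``), and the true
displacement magnitude.  Cohort and expression generators couple this
imaging truth to survival and genomics so the downstream statistics have a
recoverable truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd

from .errors import DataError
from .volume_io import (
    DisplacementField,
    LabelVolume,
    ScalarVolume,
    VolumeGrid,
    compose_fields,
    sample_field_world,
    sample_volume_world,
)

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "make_grid",
    "make_template",
    "make_subject",
    "make_cohort",
    "make_expression",
    "radial_velocity",
    "integrate_velocity",
    "flow_points",
]

#: regularization of the radial unit vector at the tumor center (mm)
EPS_MM = 1e-6
#: number of squarings for scaling-and-squaring integration
N_SQUARINGS = 6

# template geometry (world mm, head centered at the origin)
HEAD_SEMI_AXES = (50.0, 60.0, 48.0)
SKULL_FRACTION = 0.92          # inner edge of the bright skull shell
VENTRICLE_CENTER = (10.0, -8.0, 6.0)   # right ventricle; left is mirrored in x
VENTRICLE_SEMI_AXES = (6.0, 18.0, 8.0)
INTENSITY = {"background": 0.0, "parenchyma": 0.8, "skull": 1.0,
             "csf": 0.1, "tumor": 1.3}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one tumor-bearing phantom subject.

    ``amplitude`` is the peak speed (mm over unit integration time) of the
    outward mass-effect push; the realized peak displacement is close to it.
    ``falloff_sigma`` controls how far the push reaches.
    """

    tumor_center: tuple[float, float, float]
    tumor_radius: float
    amplitude: float
    falloff_sigma: float = 25.0
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: float = 2.0
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.tumor_radius <= 0:
            raise DataError("tumor_radius must be > 0")
        if self.amplitude < 0:
            raise DataError("amplitude must be >= 0")
        if self.falloff_sigma <= 0:
            raise DataError("falloff_sigma must be > 0")
        if self.noise_sd < 0:
            raise DataError("noise_sd must be >= 0")
        # scaling-and-squaring step bound: the scaled velocity step must be
        # under half a voxel for the composition to stay diffeomorphic
        bound = 0.5 * self.spacing_mm * 2 ** N_SQUARINGS
        if self.amplitude >= bound:
            raise DataError(
                f"amplitude {self.amplitude} mm exceeds the invertibility "
                f"bound {bound} mm for spacing {self.spacing_mm} mm"
            )
        c = np.asarray(self.tumor_center, float)
        if np.sum((c / np.asarray(HEAD_SEMI_AXES)) ** 2) >= 1.0:
            raise DataError("tumor center lies outside the head ellipsoid")


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth attached to a phantom subject."""

    field: DisplacementField                  # phi - id on the template grid
    inverse_field: DisplacementField          # phi**-1 - id (exact, from -v)
    true_lvd_mm: float
    true_displacement: np.ndarray             # subject COM - template COM (mm)
    true_lv_com_subject: np.ndarray
    lv_com_template: np.ndarray
    subject_lv: LabelVolume
    tumor_mask: LabelVolume = dataclass_field(repr=False, default=None)


# ---------------------------------------------------------------------------
# template
# ---------------------------------------------------------------------------

def make_grid(shape: tuple[int, int, int] = (64, 64, 64),
              spacing_mm: float = 2.0,
              space_label: str = "template") -> VolumeGrid:
    """Isotropic axis-aligned grid whose world origin is the grid center."""
    shape = tuple(int(s) for s in shape)
    affine = np.eye(4)
    affine[:3, :3] *= spacing_mm
    affine[:3, 3] = -spacing_mm * (np.asarray(shape) - 1) / 2.0
    return VolumeGrid(shape=shape, affine=affine, space_label=space_label)


def _ellipsoid(dist_sq_unit: np.ndarray) -> np.ndarray:
    return dist_sq_unit <= 1.0


def make_template(
    grid_shape: tuple[int, int, int] = (64, 64, 64), spacing_mm: float = 2.0
) -> tuple[ScalarVolume, LabelVolume]:
    """Deterministic head phantom and its lateral-ventricle mask.

    The head is an outer bright "skull" shell around mid-intensity
    parenchyma; the two ventricles are dark ellipsoids mirror-symmetric
    about the mid-sagittal plane x = 0, so the combined ventricle center of
    mass has world x-component exactly 0.
    """
    grid = make_grid(grid_shape, spacing_mm)
    x = grid.voxel_centers_world()

    head_u = np.sum((x / np.asarray(HEAD_SEMI_AXES)) ** 2, axis=-1)
    head = _ellipsoid(head_u)
    inner = head_u <= SKULL_FRACTION ** 2

    vc = np.asarray(VENTRICLE_CENTER)
    va = np.asarray(VENTRICLE_SEMI_AXES)
    right = _ellipsoid(np.sum(((x - vc) / va) ** 2, axis=-1))
    left = _ellipsoid(np.sum(((x - vc * np.array([-1, 1, 1])) / va) ** 2, axis=-1))
    lv = (right | left) & inner

    values = np.full(grid.shape, INTENSITY["background"])
    values[head] = INTENSITY["skull"]
    values[inner] = INTENSITY["parenchyma"]
    values[lv] = INTENSITY["csf"]

    return (
        ScalarVolume(grid=grid, values=values),
        LabelVolume(grid=grid, weights=lv.astype(float), kind="binary"),
    )


# ---------------------------------------------------------------------------
# deformation model
# ---------------------------------------------------------------------------

def radial_velocity(points: np.ndarray, center: np.ndarray, amplitude: float,
                    sigma: float) -> np.ndarray:
    """Outward radial velocity ``A * exp(-d^2 / 2 sigma^2) * r_hat`` (mm).

    The unit vector is regularized by ``EPS_MM`` so the field is smooth at
    the tumor center (where it vanishes by symmetry).
    """
    r = np.asarray(points, float) - np.asarray(center, float)
    d = np.linalg.norm(r, axis=-1, keepdims=True)
    return amplitude * np.exp(-(d ** 2) / (2.0 * sigma ** 2)) * r / (d + EPS_MM)


def integrate_velocity(grid: VolumeGrid, velocity: np.ndarray,
                       n_squarings: int = N_SQUARINGS) -> DisplacementField:
    """Integrate a stationary velocity field by scaling-and-squaring.

    The velocity (sampled on the grid, world mm per unit time) is scaled by
    ``2**-n_squarings`` and the resulting small displacement composed with
    itself ``n_squarings`` times, yielding the displacement of the
    diffeomorphism ``exp(v)``.  Passing ``-velocity`` gives the exact
    inverse map.
    """
    u = velocity / float(2 ** n_squarings)
    fld = DisplacementField(grid=grid, vectors=u)
    for _ in range(n_squarings):
        fld = compose_fields(fld, fld)
    return fld


def radial_divergence(points: np.ndarray, center, amplitude: float,
                      sigma: float) -> np.ndarray:
    """Analytic divergence of :func:`radial_velocity`.

    For ``v = f(d) r_hat``, ``div v = f'(d) + 2 f(d) / d``; with the
    regularized profile ``f = A exp(-d^2/2s^2) d/(d+eps)`` this is
    ``A exp(-d^2/2s^2) [2/(d+eps) + eps/(d+eps)^2 - d^2/(s^2 (d+eps))]``.
    """
    r = np.asarray(points, float) - np.asarray(center, float)
    d = np.linalg.norm(r, axis=-1)
    g = np.exp(-(d ** 2) / (2.0 * sigma ** 2))
    de = d + EPS_MM
    return amplitude * g * (2.0 / de + EPS_MM / de ** 2 - d ** 2 / (sigma ** 2 * de))


def flow_points(points: np.ndarray, center, amplitude: float, sigma: float,
                n_steps: int = 16, with_jacobian: bool = False):
    """Push points through ``exp(v)`` by RK4 integration of the analytic
    velocity — grid-free, used as the independent push-forward oracle and
    for fast cohort truth.

    With ``with_jacobian=True`` also integrates ``d log J / dt = div v``
    along each trajectory and returns ``(points, J)`` where ``J`` is the
    Jacobian determinant ``|det D phi|`` at each start point — the local
    volume-change factor needed to turn particle averages into region
    (volume-weighted) averages.
    """
    x = np.asarray(points, float).copy()
    logj = np.zeros(x.shape[:-1])
    h = 1.0 / n_steps

    def v(p):
        return radial_velocity(p, center, amplitude, sigma)

    def dv(p):
        return radial_divergence(p, center, amplitude, sigma)

    for _ in range(n_steps):
        k1 = v(x)
        k2 = v(x + 0.5 * h * k1)
        k3 = v(x + 0.5 * h * k2)
        k4 = v(x + h * k3)
        if with_jacobian:
            j1 = dv(x)
            j2 = dv(x + 0.5 * h * k1)
            j3 = dv(x + 0.5 * h * k2)
            j4 = dv(x + h * k3)
            logj = logj + (h / 6.0) * (j1 + 2 * j2 + 2 * j3 + j4)
        x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    if with_jacobian:
        return x, np.exp(logj)
    return x


def pushforward_com(lv_pts: np.ndarray, center, amplitude: float,
                    sigma: float) -> np.ndarray:
    """True center of mass of the deformed ventricle region.

    The warped region's centroid weights each source point by the local
    volume change ``|det D phi|`` — a plain mean of pushed particles would
    be biased wherever the deformation compresses or expands the
    ventricle.
    """
    pushed, jac = flow_points(lv_pts, center, amplitude, sigma,
                              with_jacobian=True)
    return (jac[:, None] * pushed).sum(axis=0) / jac.sum()


def _mask_com(mask: LabelVolume) -> np.ndarray:
    x = mask.grid.voxel_centers_world()
    w = mask.weights
    return (w[..., None] * x).sum(axis=(0, 1, 2)) / w.sum()


def make_subject(
    spec: PhantomSpec,
) -> tuple[ScalarVolume, LabelVolume, PhantomTruth]:
    """Build one tumor-bearing subject with its ground truth.

    The subject image is the template resampled through ``phi**-1`` (tissue
    at template point x appears at phi(x) in the subject), with a bright
    tumor sphere painted at the tumor center and seeded Gaussian noise.
    """
    template, lv = make_template(spec.grid_shape, spec.spacing_mm)
    grid = template.grid
    x = grid.voxel_centers_world()
    c = np.asarray(spec.tumor_center, float)

    # tumor must not engulf a ventricle
    vc = np.asarray(VENTRICLE_CENTER)
    for side in (1.0, -1.0):
        vcen = vc * np.array([side, 1.0, 1.0])
        vpts = x[lv.weights > 0]
        vside = vpts[np.sign(vpts[:, 0] - 0) == np.sign(vcen[0])] \
            if vcen[0] != 0 else vpts
        inside = np.linalg.norm(vside - c, axis=-1) <= spec.tumor_radius
        if vside.shape[0] and inside.mean() > 0.5:
            raise DataError("ventricle engulfed: tumor overlaps > 50% of a ventricle")

    vel = radial_velocity(x, c, spec.amplitude, spec.falloff_sigma)
    fwd = integrate_velocity(grid, vel)
    inv = integrate_velocity(grid, -vel)

    subj_vals = sample_volume_world(template.values, grid, x + inv.vectors)
    tumor = np.linalg.norm(x - c, axis=-1) <= spec.tumor_radius
    subj_vals[tumor] = INTENSITY["tumor"]
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        subj_vals = subj_vals + rng.normal(0.0, spec.noise_sd, size=subj_vals.shape)

    tumor_mask = LabelVolume(grid=grid, weights=tumor.astype(float), kind="binary")

    # push-forward truth: volume-weighted centroid of the deformed
    # ventricle region, from the analytic flow (grid-free)
    lv_pts = x[lv.weights > 0]
    com_t = _mask_com(lv)
    com_s = pushforward_com(lv_pts, c, spec.amplitude, spec.falloff_sigma)
    disp = com_s - com_t

    subj_lv_w = sample_volume_world(lv.weights, grid, x + inv.vectors)
    subj_lv = LabelVolume(
        grid=grid, weights=(subj_lv_w >= 0.5).astype(float), kind="binary"
    )

    truth = PhantomTruth(
        field=fwd,
        inverse_field=inv,
        true_lvd_mm=float(np.linalg.norm(disp)),
        true_displacement=disp,
        true_lv_com_subject=com_s,
        lv_com_template=com_t,
        subject_lv=subj_lv,
        tumor_mask=tumor_mask,
    )
    return ScalarVolume(grid=grid, values=subj_vals), tumor_mask, truth


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

# survival couplings: age and performance-status effects sized like those
# typically reported for glioblastoma (HR ~1.02/yr of age, ~0.98/KPS point)
BETA_AGE = 0.022
BETA_KPS = -0.024
BASELINE_MEDIAN_OS_DAYS = 400.0
BASELINE_MEDIAN_PFS_DAYS = 230.0


def sample_spec(rng: np.random.Generator,
                grid_shape=(64, 64, 64), spacing_mm=2.0,
                noise_sd=0.02) -> PhantomSpec:
    """Draw one tumor geometry: lateralized center, radius 8-15 mm,
    mass-effect amplitude spanning mild to severe."""
    vc = np.asarray(VENTRICLE_CENTER)
    for _ in range(200):
        side = rng.choice([-1.0, 1.0])
        center = np.array([
            side * rng.uniform(16.0, 34.0),
            rng.uniform(-22.0, 26.0),
            rng.uniform(-8.0, 16.0),
        ])
        radius = rng.uniform(8.0, 15.0)
        # push strength grows with tumor size but with wide independent
        # scatter (compliance), so LVd correlates with volume only loosely
        amplitude = radius * rng.uniform(0.3, 3.6)
        sigma = rng.uniform(20.0, 30.0)
        # inside the head with margin, clear of both ventricle centers
        in_head = np.sum(((center) / np.asarray(HEAD_SEMI_AXES)) ** 2) < 0.7 ** 2
        clear = all(
            np.linalg.norm(center - vc * np.array([s, 1, 1])) > radius + 10.0
            for s in (1.0, -1.0)
        )
        if in_head and clear:
            return PhantomSpec(
                tumor_center=tuple(center), tumor_radius=float(radius),
                amplitude=float(amplitude), falloff_sigma=float(sigma),
                grid_shape=grid_shape, spacing_mm=spacing_mm,
                noise_sd=noise_sd,
                seed=int(rng.integers(0, 2 ** 31 - 1)),
            )
    raise DataError("could not sample an admissible tumor geometry")


def validation_specs(seed: int, n: int = 20,
                     noise_sd: float = 0.02) -> list[PhantomSpec]:
    """Deterministic phantom validation suite: varied tumor geometries with
    mass-effect amplitudes evenly spanning 1-10 mm, used to benchmark the
    metric pipeline and the registration stand-in against ground truth."""
    rng = np.random.default_rng(seed)
    specs = []
    for amp in np.linspace(1.0, 10.0, n):
        base = sample_spec(rng, noise_sd=noise_sd)
        specs.append(PhantomSpec(
            tumor_center=base.tumor_center, tumor_radius=base.tumor_radius,
            amplitude=float(amp), falloff_sigma=base.falloff_sigma,
            grid_shape=base.grid_shape, spacing_mm=base.spacing_mm,
            noise_sd=noise_sd, seed=base.seed,
        ))
    return specs


def true_lvd_for_spec(spec: PhantomSpec, lv_pts: np.ndarray,
                      com_t: np.ndarray) -> tuple[float, np.ndarray]:
    """Ground-truth LVd for a spec without building image volumes:
    volume-weighted RK4 push-forward of the template ventricle voxel
    centers."""
    com_s = pushforward_com(lv_pts, spec.tumor_center, spec.amplitude,
                            spec.falloff_sigma)
    disp = com_s - com_t
    return float(np.linalg.norm(disp)), disp


def make_cohort(
    n: int,
    seed: int,
    lvd_log_hazard: float,
    beta_age: float = BETA_AGE,
    beta_kps: float = BETA_KPS,
    grid_shape=(64, 64, 64),
    spacing_mm: float = 2.0,
) -> tuple[pd.DataFrame, list[PhantomSpec]]:
    """Sample a synthetic cohort with proportional-hazards survival truth.

    Per subject: a tumor geometry (true LVd spread roughly 1-20 mm), age,
    KPS, tumor volumes (CEV = sphere volume; FHV = dilated sphere volume,
    so the LVd-volume correlation is positive but imperfect), and OS/PFS
    drawn from exponential models with
    ``log-hazard = lvd_log_hazard * LVd + beta_age * (age-60) +
    beta_kps * (KPS-80)`` plus independent uniform censoring.
    """
    if n < 2:
        raise DataError("cohort needs n >= 2")
    rng = np.random.default_rng(seed)
    _, lv = make_template(grid_shape, spacing_mm)
    lv_pts = lv.grid.voxel_centers_world()[lv.weights > 0]
    com_t = _mask_com(lv)

    specs, rows = [], []
    for i in range(n):
        spec = sample_spec(rng, grid_shape, spacing_mm)
        lvd, disp = true_lvd_for_spec(spec, lv_pts, com_t)
        age = float(np.clip(rng.normal(60.0, 12.0), 18.0, 90.0))
        kps = float(np.clip(np.round(rng.normal(80.0, 15.0) / 10.0) * 10.0,
                            40.0, 100.0))
        linpred = lvd_log_hazard * lvd + beta_age * (age - 60.0) \
            + beta_kps * (kps - 80.0)
        h_os = np.log(2.0) / BASELINE_MEDIAN_OS_DAYS * np.exp(linpred)
        h_pfs = np.log(2.0) / BASELINE_MEDIAN_PFS_DAYS * np.exp(linpred)
        t_os = rng.exponential(1.0 / h_os)
        t_pfs = rng.exponential(1.0 / h_pfs)
        c_os = rng.uniform(60.0, 1500.0)
        c_pfs = rng.uniform(40.0, 1000.0)
        cev = 4.0 / 3.0 * np.pi * spec.tumor_radius ** 3
        fhv = 4.0 / 3.0 * np.pi * (spec.tumor_radius + 8.0) ** 3

        rows.append({
            "id": f"P{i:04d}",
            "lvd_mm": lvd,
            "lvx_mm": abs(disp[0]),
            "cev_mm3": cev,
            "fhv_mm3": fhv,
            "age_years": age,
            "kps": kps,
            "os_days": max(1.0, round(min(t_os, c_os))),
            "os_event": int(t_os <= c_os),
            "pfs_days": max(1.0, round(min(t_pfs, c_pfs))),
            "pfs_event": int(t_pfs <= c_pfs),
        })
        specs.append(spec)
    return pd.DataFrame(rows), specs


# ---------------------------------------------------------------------------
# expression generator
# ---------------------------------------------------------------------------

def make_expression(
    groups: np.ndarray,
    n_genes: int = 2000,
    n_signal: int = 0,
    effect_size: float = 0.0,
    seed: int = 0,
    sample_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Gaussian log-expression matrix (genes x samples) with planted signal.

    The first ``n_signal`` (randomly chosen) genes are shifted upward by
    ``effect_size`` (in SD units of the unit-variance noise) in the
    ``groups == 1`` samples; all other genes are null.  Returns the matrix
    and the list of true signal gene ids.
    """
    groups = np.asarray(groups).astype(int)
    if n_signal > n_genes:
        raise DataError("n_signal cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    n_samples = groups.size
    mat = rng.normal(0.0, 1.0, size=(n_genes, n_samples))
    signal_idx = rng.choice(n_genes, size=n_signal, replace=False)
    mat[np.ix_(signal_idx, np.flatnonzero(groups == 1))] += effect_size
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    df = pd.DataFrame(mat, index=gene_ids, columns=sample_ids)
    return df, [gene_ids[i] for i in sorted(signal_idx)]
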