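"""Volume/field I/O round-trips, the coordinate contract, and mask warping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ventridisp.errors import DataError
from ventridisp.phantom import integrate_velocity, make_grid, radial_velocity
from ventridisp.volume_io import (
    DisplacementField,
    LabelVolume,
    ScalarVolume,
    VolumeGrid,
    compose_fields,
    invert_field,
    read_field,
    read_volume,
    sample_field_world,
    voxel_to_world,
    warp_mask,
    world_to_voxel,
    write_field,
    write_volume,
)


def _random_grid(rng):
    lin = rng.normal(0, 1, (3, 3)) + 3 * np.eye(3)
    affine = np.eye(4)
    affine[:3, :3] = lin
    affine[:3, 3] = rng.normal(0, 10, 3)
    return VolumeGrid(shape=(5, 6, 7), affine=affine)


class TestCoordinates:
    def test_identity_affine_maps_index_to_itself(self):
        grid = VolumeGrid(shape=(16, 16, 16), affine=np.eye(4))
        assert np.allclose(voxel_to_world(grid, [10, 10, 10]), [10, 10, 10])

    def test_scaled_translated_affine(self):
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        affine[:3, 3] = [1.0, 0.0, 0.0]
        grid = VolumeGrid(shape=(8, 8, 8), affine=affine)
        assert np.allclose(voxel_to_world(grid, [0, 0, 0]), [1, 0, 0])

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_world_to_voxel_inverts_voxel_to_world(self, seed):
        rng = np.random.default_rng(seed)
        grid = _random_grid(rng)
        idx = rng.uniform(0, 5, (20, 3))
        back = world_to_voxel(grid, voxel_to_world(grid, idx))
        assert np.allclose(back, idx, atol=1e-9)

    def test_singular_affine_rejected(self):
        affine = np.eye(4)
        affine[0, 0] = 0.0
        with pytest.raises(DataError):
            VolumeGrid(shape=(4, 4, 4), affine=affine)


class TestVolumeRoundTrip:
    def test_scalar_volume_roundtrip(self, tmp_path):
        rng = np.random.default_rng(3)
        grid = _random_grid(rng)
        vol = ScalarVolume(grid=grid, values=rng.normal(0, 1, grid.shape))
        for name in ("v.nii", "v.nii.gz"):
            path = tmp_path / name
            write_volume(vol, path)
            back = read_volume(path)
            assert np.allclose(back.values, vol.values, atol=1e-6)
            assert np.allclose(back.grid.affine, grid.affine, atol=1e-6)

    def test_binary_mask_roundtrip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(4)
        grid = make_grid((12, 12, 12))
        mask = LabelVolume(grid=grid,
                           weights=(rng.random(grid.shape) > 0.7).astype(float),
                           kind="binary")
        path = tmp_path / "m.nii.gz"
        write_volume(mask, path)
        back = read_volume(path, as_label="binary")
        assert back.kind == "binary"
        assert np.array_equal(back.weights, mask.weights)

    def test_missing_file_and_bad_label(self, tmp_path):
        with pytest.raises(DataError, match="no such file"):
            read_volume(tmp_path / "absent.nii")
        grid = make_grid((4, 4, 4))
        vol = ScalarVolume(grid=grid, values=np.full(grid.shape, 0.5))
        path = tmp_path / "half.nii"
        write_volume(vol, path)
        with pytest.raises(DataError, match="binary"):
            read_volume(path, as_label="binary")

    def test_nonfinite_voxels_reported_with_count(self):
        grid = make_grid((4, 4, 4))
        values = np.zeros(grid.shape)
        values[0, 0, 0] = np.nan
        values[1, 1, 1] = np.inf
        with pytest.raises(DataError, match="2 non-finite"):
            ScalarVolume(grid=grid, values=values)


class TestFieldRoundTrip:
    def test_zero_and_random_field_roundtrip(self, tmp_path):
        grid = make_grid((10, 10, 10))
        rng = np.random.default_rng(5)
        for vectors in (np.zeros(grid.shape + (3,)),
                        rng.normal(0, 2, grid.shape + (3,))):
            fld = DisplacementField(grid=grid, vectors=vectors)
            path = tmp_path / "f.nii.gz"
            write_field(fld, path)
            back = read_field(path)
            assert np.allclose(back.vectors, vectors, atol=1e-6)

    def test_wrong_dialect_reports_expected_dims(self, tmp_path):
        import nibabel as nib
        data = np.zeros((4, 4, 4, 3))
        nib.save(nib.Nifti1Image(data, np.eye(4)), tmp_path / "bad.nii")
        with pytest.raises(DataError, match=r"\[X,Y,Z,1,3\]"):
            read_field(tmp_path / "bad.nii")


def _phantom_field(amplitude=6.0, shape=(72, 72, 72), spacing=1.0):
    # ~1 mm resolution: the Dice bounds below assume interpolation loss only
    grid = make_grid(shape, spacing)
    vel = radial_velocity(grid.voxel_centers_world(), (20.0, 0.0, 0.0),
                          amplitude, 25.0)
    return grid, integrate_velocity(grid, vel)


def _interior_ball_mask(grid, center=(0.0, 0.0, 0.0), radius=18.0):
    x = grid.voxel_centers_world()
    w = (np.linalg.norm(x - np.asarray(center), axis=-1) <= radius).astype(float)
    return LabelVolume(grid=grid, weights=w, kind="binary")


def _dice(a, b):
    a, b = a > 0, b > 0
    return 2 * (a & b).sum() / (a.sum() + b.sum())


class TestWarpMask:
    def test_zero_field_is_identity_bit_exact(self):
        grid = make_grid((20, 20, 20))
        mask = _interior_ball_mask(grid, radius=12.0)
        fld = DisplacementField(grid=grid, vectors=np.zeros(grid.shape + (3,)))
        out = warp_mask(mask, fld)
        assert np.array_equal(out.weights, mask.weights)

    def test_constant_translation_moves_com_exactly(self):
        grid = make_grid((32, 32, 32))
        mask = _interior_ball_mask(grid, radius=10.0)
        u = np.zeros(grid.shape + (3,))
        u[...] = [3.0, 4.0, 0.0]
        out = warp_mask(mask, DisplacementField(grid=grid, vectors=u))
        x = grid.voxel_centers_world()
        com_in = (mask.weights[..., None] * x).sum((0, 1, 2)) / mask.weights.sum()
        com_out = (out.weights[..., None] * x).sum((0, 1, 2)) / out.weights.sum()
        assert np.allclose(com_out - com_in, [3.0, 4.0, 0.0], atol=1e-6)

    def test_radial_field_matches_pushforward_binning_oracle(self):
        grid, fld = _phantom_field()
        mask = _interior_ball_mask(grid, radius=20.0)
        out = warp_mask(mask, fld)
        # oracle: map supersampled mask voxel centers through phi, bin
        idx = np.argwhere(mask.weights > 0).astype(float)
        offsets = np.stack(np.meshgrid(*[[-0.25, 0.25]] * 3, indexing="ij"),
                           axis=-1).reshape(-1, 3)
        pts = (idx[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
        world = voxel_to_world(grid, pts)
        pushed = world + sample_field_world(fld, world)
        vox = np.round(world_to_voxel(grid, pushed)).astype(int)
        vox = np.clip(vox, 0, np.array(grid.shape) - 1)
        oracle = np.zeros(grid.shape)
        oracle[tuple(vox.T)] = 1.0
        assert _dice(out.weights, oracle) >= 0.95

    def test_warp_then_inverse_warp_recovers_mask(self):
        grid, fld = _phantom_field()
        inv = invert_field(fld)
        mask = _interior_ball_mask(grid, radius=20.0)
        there = warp_mask(mask, fld)
        back = warp_mask(there, inv)
        assert _dice(back.weights, mask.weights) >= 0.98

    def test_commutes_with_world_translation(self):
        grid, fld = _phantom_field(shape=(32, 32, 32), spacing=4.0)
        mask = _interior_ball_mask(grid, radius=16.0)
        warped = warp_mask(mask, fld)
        shifted_affine = grid.affine.copy()
        shifted_affine[:3, 3] += [7.0, -3.0, 2.0]
        sgrid = VolumeGrid(shape=grid.shape, affine=shifted_affine)
        smask = LabelVolume(grid=sgrid, weights=mask.weights, kind="binary")
        sfld = DisplacementField(grid=sgrid, vectors=fld.vectors)
        swarped = warp_mask(smask, sfld)
        # same voxel pattern, expressed on the translated grid
        assert np.array_equal(swarped.weights, warped.weights)

    def test_mismatched_grids_rejected(self):
        grid = make_grid((8, 8, 8))
        other = make_grid((8, 8, 8), 3.0)
        mask = _interior_ball_mask(grid, radius=8.0)
        fld = DisplacementField(grid=other, vectors=np.zeros(other.shape + (3,)))
        with pytest.raises(DataError, match="share a grid"):
            warp_mask(mask, fld)


class TestFieldAlgebra:
    def test_compose_of_translations_adds(self):
        grid = make_grid((12, 12, 12))
        u1 = np.zeros(grid.shape + (3,))
        u1[...] = [1.0, 2.0, 0.0]
        u2 = np.zeros(grid.shape + (3,))
        u2[...] = [0.5, -1.0, 3.0]
        f = compose_fields(DisplacementField(grid=grid, vectors=u1),
                           DisplacementField(grid=grid, vectors=u2))
        assert np.allclose(f.vectors, [1.5, 1.0, 3.0], atol=1e-9)

    def test_invert_translation_field(self):
        grid = make_grid((12, 12, 12))
        u = np.zeros(grid.shape + (3,))
        u[...] = [3.0, 4.0, 0.0]
        inv = invert_field(DisplacementField(grid=grid, vectors=u))
        assert np.allclose(inv.vectors, [-3.0, -4.0, 0.0], atol=0.05)

    def test_invert_radial_field_roundtrip(self):
        grid, fld = _phantom_field(shape=(32, 32, 32), spacing=4.0)
        inv = invert_field(fld)
        x = grid.voxel_centers_world()
        fwd_pts = x + fld.vectors
        round_trip = fwd_pts + sample_field_world(inv, fwd_pts)
        err = np.linalg.norm(round_trip - x, axis=-1)
        interior = np.linalg.norm(x, axis=-1) < 40
        assert np.percentile(err[interior], 99) < 0.3
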