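"""Segmentation, serial differencing, reconstruction and file round-trips."""

import numpy as np
import pytest

from depotkit.errors import EmptyReconstruction, InvalidSpec, NoDepotFound
from depotkit.phantoms import DepotSpec, SpeckleParams, make_depot_phantom, make_us_frames, sweep_poses
from depotkit.volumetric import (
    BinaryMask,
    TrackedFrame,
    VoxelVolume,
    read_mask,
    read_poses_csv,
    read_volume,
    reconstruct_volume,
    segment_depot,
    serial_increments,
    write_mask,
    write_poses_csv,
    write_volume,
)

from conftest import make_ball_mask


def ball_volume(radius_mm=10.0, spacing=1.0, hu_in=800.0, hu_bg=50.0, center=(0.0, 0.0, 0.0)):
    n = int(np.ceil((radius_mm + 4) / spacing))
    ax = np.arange(-n, n + 1) * spacing
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
    inside = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2 <= radius_mm**2
    values = np.where(inside, hu_in, hu_bg)
    origin = (-n * spacing,) * 3
    return VoxelVolume(values, (spacing,) * 3, origin), inside


class TestSegmentation:
    def test_phantom_depot_volume_within_2pct(self, default_phantom):
        vol, truth = default_phantom
        mask = segment_depot(vol, 300.0, 2000.0)
        assert mask.volume_ml == pytest.approx(truth.volume_ml, rel=0.02)

    def test_uniform_background_raises(self):
        vol = VoxelVolume(np.full((8, 8, 8), 50.0), (1, 1, 1))
        with pytest.raises(NoDepotFound):
            segment_depot(vol, 300.0, 2000.0)

    def test_two_disjoint_depots_select_all(self):
        ax = np.arange(-16, 17, dtype=float)
        z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
        big = (x + 8) ** 2 + y**2 + z**2 <= 5**2
        small = (x - 8) ** 2 + y**2 + z**2 <= 3**2
        vol = VoxelVolume(np.where(big | small, 800.0, 50.0), (1.0, 1.0, 1.0))
        comps = segment_depot(vol, 300.0, 2000.0, select="all")
        assert len(comps) == 2
        # voxel-count oracle per constructed ball
        assert comps[0].values.sum() == big.sum()
        assert comps[1].values.sum() == small.sum()

    def test_idempotent_on_mask_rendered_volume(self, ball_mask):
        rendered = VoxelVolume(np.where(ball_mask.values, 800.0, 50.0), ball_mask.spacing)
        again = segment_depot(rendered, 300.0, 2000.0)
        assert np.array_equal(again.values, ball_mask.values)

    def test_invalid_threshold_order(self, ball_mask):
        rendered = VoxelVolume(ball_mask.values.astype(float), ball_mask.spacing)
        with pytest.raises(InvalidSpec):
            segment_depot(rendered, 10.0, 1.0)


class TestSerialIncrements:
    def _nested_balls(self, target_mls=(1.0, 2.0, 3.0, 4.0), spacing=0.6):
        radii = [(3 * v * 1000 / (4 * np.pi)) ** (1 / 3) for v in target_mls]
        n = int(np.ceil((max(radii) + 2) / spacing))
        ax = np.arange(-n, n + 1) * spacing
        z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
        r2 = x**2 + y**2 + z**2
        return [BinaryMask(r2 <= r**2, (spacing,) * 3) for r in radii]

    def test_nested_balls_increment_about_1ml(self):
        masks = self._nested_balls()
        incs = serial_increments(masks)
        for inc in incs:
            assert inc.volume_ml == pytest.approx(1.0, rel=0.05)

    def test_identical_masks_zero_increment(self, ball_mask):
        incs = serial_increments([ball_mask, ball_mask])
        assert incs[0].volume_ml == 0.0

    def test_new_lobe_appears_exactly_in_increment(self):
        masks = self._nested_balls(target_mls=(1.0, 2.0))
        lobe = np.zeros_like(masks[0].values)
        lobe[2:6, 2:6, 2:6] = True
        with_lobe = BinaryMask(masks[1].values | lobe, masks[1].spacing)
        inc = serial_increments([masks[0], with_lobe])[0]
        expected = (masks[1].values | lobe) & ~masks[0].values
        assert np.array_equal(inc.values, expected)

    def test_shrinking_series_warns(self, ball_mask):
        from scipy import ndimage

        small = BinaryMask(
            ndimage.binary_erosion(ball_mask.values, iterations=3), ball_mask.spacing
        )
        with pytest.warns(UserWarning, match="non-monotone"):
            serial_increments([ball_mask, small])

    def test_alignment_transforms_consumed(self, ball_mask):
        # shift the second mask by a known translation; alignment undoes it
        shifted = BinaryMask(np.roll(ball_mask.values, 4, axis=2), ball_mask.spacing)
        dx = 4 * ball_mask.spacing[2]
        eye = np.eye(3)
        incs = serial_increments(
            [ball_mask, shifted],
            alignment=[(eye, np.zeros(3)), (eye, np.array([-dx, 0.0, 0.0]))],
        )
        assert incs[0].volume_ml == pytest.approx(0.0, abs=1e-9)


@pytest.fixture(scope="module")
def ball_phantom():
    return make_depot_phantom(DepotSpec(semi_axes=(10.0, 10.0, 10.0), spacing=0.75, margin=5.0))


class TestReconstruction:
    def _sweep(self, vol, step, frame_shape=None):
        nz = vol.shape[0] * vol.spacing[0]
        n = int(np.ceil(nz / step)) + 1
        poses = sweep_poses(n, step, vol.spacing[2], (vol.origin[0], vol.origin[1], vol.origin[2]))
        return make_us_frames(
            vol, poses, SpeckleParams(enabled=False), frame_shape=frame_shape or vol.shape[1:]
        )

    def test_dense_sweep_volume_within_5pct(self, ball_phantom):
        vol, truth = ball_phantom
        frames = self._sweep(vol, step=0.75)
        recon, _ = reconstruct_volume(frames, out_spacing=0.75)
        mask = segment_depot(recon, 130.0, 300.0)
        assert mask.volume_ml == pytest.approx(truth.volume_ml, rel=0.05)

    def test_error_decreases_with_sweep_density(self, ball_phantom):
        vol, truth = ball_phantom
        errs = []
        for step in (1.0, 2.0, 3.0):
            recon, _ = reconstruct_volume(self._sweep(vol, step), out_spacing=0.75)
            mask = segment_depot(recon, 130.0, 300.0)
            errs.append(abs(mask.volume_ml - truth.volume_ml) / truth.volume_ml)
        assert errs[0] < errs[1] < errs[2]

    def test_rotated_sweep_agrees_with_axis_aligned(self, ball_phantom):
        vol, truth = ball_phantom
        axis = segment_depot(
            reconstruct_volume(self._sweep(vol, 0.75), out_spacing=0.75)[0], 130.0, 300.0
        )
        th = np.deg2rad(30)
        R = np.array([[np.cos(th), 0, np.sin(th)], [0, 1, 0], [-np.sin(th), 0, np.cos(th)]])
        L, px, m = 40.0, 0.75, 64
        start = -L / 2 * R[:, 2] - m * px / 2 * R[:, 0] - m * px / 2 * R[:, 1]
        poses = [
            {"frame_id": i, "rotation": R, "translation": start + i * 0.5 * R[:, 2], "pixel_spacing": px}
            for i in range(int(L / 0.5) + 1)
        ]
        frames = make_us_frames(vol, poses, SpeckleParams(enabled=False), frame_shape=(m, m))
        rot = segment_depot(reconstruct_volume(frames, out_spacing=0.75)[0], 130.0, 300.0)
        assert rot.volume_ml == pytest.approx(axis.volume_ml, rel=0.10)

    def test_single_repeated_frame_degenerates_to_plane(self, ball_phantom):
        vol, _ = ball_phantom
        k = vol.shape[0] // 2
        poses = sweep_poses(1, 1.0, vol.spacing[2], (vol.origin[0], vol.origin[1], vol.origin[2] + k * vol.spacing[0]))
        f = make_us_frames(vol, poses, SpeckleParams(enabled=False), frame_shape=vol.shape[1:])[0]
        recon, visited = reconstruct_volume([f, f], out_spacing=0.75)
        ks = np.unique(np.nonzero(visited.values)[0])
        assert len(ks) <= 3  # all mass within the 1-voxel kernel of one plane

    def test_all_frames_outside_extent_raises(self, ball_phantom):
        vol, _ = ball_phantom
        frames = self._sweep(vol, step=2.0)
        with pytest.raises(EmptyReconstruction):
            reconstruct_volume(frames, out_spacing=0.75, out_shape=(5, 5, 5), out_origin=(900.0, 900.0, 900.0))


class TestIO:
    @pytest.mark.parametrize("ext", ["nii.gz", "mha"])
    def test_volume_round_trip(self, tmp_path, ext):
        vol = VoxelVolume(
            np.arange(60, dtype=float).reshape(3, 4, 5),
            (2.0, 1.0, 0.5),
            (10.0, -5.0, 3.0),
        )
        p = tmp_path / f"vol.{ext}"
        write_volume(vol, p)
        back = read_volume(p)
        np.testing.assert_allclose(back.values, vol.values)
        np.testing.assert_allclose(back.spacing, vol.spacing)
        np.testing.assert_allclose(back.origin, vol.origin)

    def test_mask_round_trip(self, tmp_path, ball_mask):
        p = tmp_path / "mask.nii.gz"
        write_mask(ball_mask, p)
        back = read_mask(p)
        assert np.array_equal(back.values, ball_mask.values)

    def test_poses_round_trip(self, tmp_path):
        th = np.deg2rad(20)
        R = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        frames = [
            TrackedFrame(np.zeros((4, 4), np.uint8), 0.4, R, np.array([1.0, 2.0, 3.0]), frame_id=5)
        ]
        p = tmp_path / "poses.csv"
        write_poses_csv(frames, p)
        back = read_poses_csv(p)[0]
        assert back["frame_id"] == 5
        np.testing.assert_allclose(back["rotation"], R)
        np.testing.assert_allclose(back["translation"], [1.0, 2.0, 3.0])
        assert back["pixel_spacing"] == pytest.approx(0.4)

    def test_world_index_round_trip(self, default_phantom):
        vol, _ = default_phantom
        kji = np.array([[3.0, 4.0, 5.0], [0.0, 0.0, 0.0]])
        np.testing.assert_allclose(vol.world_to_index(vol.index_to_world(kji)), kji, atol=1e-12)
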