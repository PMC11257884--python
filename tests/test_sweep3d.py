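"""Fan-sweep capture, volume reconstruction, and oblique reslicing."""

import numpy as np
import pytest

from echoguide.geometry import Pose, compose, pose_error
from echoguide.phantom import ImageGeometry, OrganSpec, Phantom, make_phantom, organ_visibility
from echoguide.sweep3d import (
    SweepSpec,
    best_plane_search,
    capture_sweep,
    extract_plane,
    fan_pose,
    reconstruct,
)

GEO = ImageGeometry(depth_mm=80, width_mm=60, pixel_mm=1.0)


def constant_phantom(value=0.5):
    """Uniform echogenicity field, no organs, no texture."""
    shape = (60, 60, 50)
    return Phantom(
        grid=np.full(shape, value, np.float32),
        label_grid=np.zeros(shape, np.int16),
        spacing_mm=2.0,
        origin_mm=np.array([-60.0, -60.0, 0.0]),
        specs=[],
    )


def base_pose(x=0.0, y=0.0):
    return Pose(np.array([1.0, 0, 0, 0]), (x, y, 0.0), "body", "probe_cube")


@pytest.fixture(scope="module")
def wide_organ_phantom():
    """Single organ with a wide-open window: no aperture shadowing of any frame."""
    spec = OrganSpec("kidney", (0, 0, 45), (22, 18, 14), 0.7, 90.0)
    return make_phantom([spec], spacing_mm=2.0, seed=2,
                        bounds=((-70, 70), (-70, 70), (0, 100)), geometry=GEO)


class TestSweepSpec:
    @pytest.mark.parametrize("kwargs", [{"n_frames": 1}, {"fan_half_angle_deg": 0.0},
                                        {"fan_half_angle_deg": 75.0}])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SweepSpec(**kwargs)

    def test_middle_frame_of_odd_sweep_is_the_base_pose(self, wide_organ_phantom):
        stack = capture_sweep(wide_organ_phantom, base_pose(), SweepSpec(20, 9), GEO)
        err = pose_error(stack.poses[4], base_pose())
        assert err.translation_mm < 1e-12 and err.rotation_deg < 1e-9


class TestReconstruct:
    def test_constant_field_reproduced_exactly(self):
        stack = capture_sweep(constant_phantom(0.5), base_pose(), SweepSpec(25, 30), GEO,
                              mu_per_mm=0.0)
        vol = reconstruct(stack, voxel_mm=2.0)
        # interior voxels only: the top millimetres of each frame blend with
        # the zero padding outside the phantom grid
        shape = vol.data.shape
        ax = [(np.arange(s) + 0.5) * vol.voxel_mm for s in shape]
        pts = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1).reshape(-1, 3)
        z_body = vol.origin_pose.apply(pts)[:, 2].reshape(shape)
        sel = vol.fill & (z_body > 5.0) & (z_body < 70.0)
        assert sel.any()
        assert np.abs(vol.data[sel] - 0.5).max() < 1e-6

    def test_dense_sweep_matches_direct_phantom_sampling(self, wide_organ_phantom):
        from scipy import ndimage

        stack = capture_sweep(wide_organ_phantom, base_pose(), SweepSpec(30, 90), GEO,
                              mu_per_mm=0.0)
        vol = reconstruct(stack, voxel_mm=1.5)
        # voxel centers -> body frame -> direct trilinear phantom samples
        shape = vol.data.shape
        ax = [(np.arange(s) + 0.5) * vol.voxel_mm for s in shape]
        pts_vol = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1).reshape(-1, 3)
        pts_body = vol.origin_pose.apply(pts_vol)
        ref = ndimage.map_coordinates(
            wide_organ_phantom.grid,
            wide_organ_phantom.voxel_coords(pts_body).T,
            order=1, cval=0.0,
        ).reshape(shape)
        err = np.abs(vol.data - ref)[vol.has_data]
        assert err.mean() <= 0.02

    def test_sparser_sweep_has_more_holes(self, wide_organ_phantom):
        dense = reconstruct(
            capture_sweep(wide_organ_phantom, base_pose(), SweepSpec(30, 90), GEO), 1.5
        )
        sparse = reconstruct(
            capture_sweep(wide_organ_phantom, base_pose(), SweepSpec(30, 3), GEO), 1.5
        )
        assert sparse.hole_fraction > dense.hole_fraction

    def test_fidelity_improves_with_frame_count(self, wide_organ_phantom):
        from scipy import ndimage

        maes = []
        for n in (5, 15, 45, 90):
            stack = capture_sweep(wide_organ_phantom, base_pose(), SweepSpec(30, n), GEO,
                                  mu_per_mm=0.0)
            vol = reconstruct(stack, voxel_mm=1.5)
            shape = vol.data.shape
            ax = [(np.arange(s) + 0.5) * vol.voxel_mm for s in shape]
            pts = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1).reshape(-1, 3)
            ref = ndimage.map_coordinates(
                wide_organ_phantom.grid,
                wide_organ_phantom.voxel_coords(vol.origin_pose.apply(pts)).T,
                order=1, cval=0.0,
            ).reshape(shape)
            # fidelity of the full reconstructed field (observed + averaged)
            maes.append(float(np.abs(vol.data - ref)[vol.has_data].mean()))
        assert maes[0] > maes[1] > maes[2] >= maes[3]

    def test_single_frame_stack_rejected(self, wide_organ_phantom):
        from echoguide.sweep3d import FrameStack

        stack = capture_sweep(wide_organ_phantom, base_pose(), SweepSpec(20, 5), GEO)
        broken = FrameStack(stack.frames[:1], stack.poses[:1], stack.spec, stack.base_pose, GEO)
        with pytest.raises(ValueError, match="at least 2"):
            reconstruct(broken)


@pytest.fixture(scope="module")
def dense_volume(wide_organ_phantom):
    stack = capture_sweep(wide_organ_phantom, base_pose(), SweepSpec(30, 60), GEO)
    return stack, reconstruct(stack, voxel_mm=1.0)


class TestExtractPlane:
    def test_reslice_at_captured_pose_matches_original_frame(self, dense_volume):
        stack, vol = dense_volume
        for idx in (10, 30, 50):
            img, valid = extract_plane(vol, stack.poses[idx], GEO)
            orig = stack.frames[idx].pixels
            assert valid.mean() > 0.8
            assert np.abs(img - orig)[valid].mean() <= 0.02

    def test_plane_outside_volume_is_empty(self, dense_volume):
        _, vol = dense_volume
        far = Pose(np.array([1.0, 0, 0, 0]), (500, 500, 0), "body", "plane")
        img, valid = extract_plane(vol, far, GEO)
        assert not valid.any() and not img.any()

    def test_parallel_planes_one_voxel_apart_differ_smoothly(self, dense_volume):
        _, vol = dense_volume
        a = Pose(np.array([1.0, 0, 0, 0]), (0, 2.0, 0), "body", "plane")
        b = Pose(np.array([1.0, 0, 0, 0]), (0, 3.0, 0), "body", "plane")
        ia, va = extract_plane(vol, a, GEO)
        ib, vb = extract_plane(vol, b, GEO)
        both = va & vb
        assert np.abs(ia - ib)[both].mean() < 0.05


class TestBestPlaneSearch:
    def test_argmax_dominates_the_base_plane(self, wide_organ_phantom):
        stack = capture_sweep(wide_organ_phantom, base_pose(), SweepSpec(30, 20), GEO)
        vol = reconstruct(stack, 2.0)
        _, best_vis = best_plane_search(vol, "kidney", wide_organ_phantom, geometry=GEO)
        assert best_vis >= organ_visibility(wide_organ_phantom, "kidney", base_pose(), GEO)

    def test_organ_off_plane_but_inside_wedge_is_rescued(self, wide_organ_phantom):
        """Direct view misses the organ; an oblique wedge plane recovers it."""
        off = base_pose(y=25.0)  # organ elevation semi-axis is 18 mm
        direct_vis = organ_visibility(wide_organ_phantom, "kidney", off, GEO)
        stack = capture_sweep(wide_organ_phantom, off, SweepSpec(35, 20), GEO)
        vol = reconstruct(stack, 2.0)
        _, best_vis = best_plane_search(vol, "kidney", wide_organ_phantom, geometry=GEO)
        assert direct_vis < 0.5
        assert best_vis > direct_vis + 0.3

    def test_unknown_organ_and_empty_grid_raise(self, wide_organ_phantom):
        stack = capture_sweep(wide_organ_phantom, base_pose(), SweepSpec(20, 5), GEO)
        vol = reconstruct(stack, 2.0)
        with pytest.raises(KeyError):
            best_plane_search(vol, "spleen", wide_organ_phantom, geometry=GEO)
        with pytest.raises(ValueError, match="empty"):
            best_plane_search(vol, "kidney", wide_organ_phantom, search_grid=[], geometry=GEO)
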