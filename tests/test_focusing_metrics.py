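"""Focusing metrics on analytically constructed volumes."""

import numpy as np
import pytest

from mitolens.focusing_metrics import (annotate_axes, concentration_profile,
                                       find_focus, osr_concentration,
                                       read_stack, write_stack)

RES = 10.0  # voxels per um for the synthetic volumes


def _gaussian_focus_volume(shape=(60, 60, 120), peak=6.6, depth=5.8,
                           tip_z=6.0, sigma_z=1.0, sigma_r=0.5,
                           background=1.0, tilt_x=0.0):
    """Background + Gaussian 'pencil' of known peak and focal depth.

    The structural channel is a cylinder (the bundle) below the tip, its axis
    optionally tilted in x; the intensity focus sits on that axis at
    ``depth`` um beyond the tip.
    """
    nx, ny, nz = shape
    x, y, z = [(np.arange(n) + 0.5) / RES for n in shape]
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    cx, cy = nx / 2 / RES, ny / 2 / RES
    xc = cx + (Z - tip_z) * np.tan(np.radians(tilt_x))
    struct = ((Z < tip_z) & (Z > tip_z - 4.0)
              & ((X - xc) ** 2 + (Y - cy) ** 2 < 1.0 ** 2)).astype(np.float32)
    zf = tip_z + depth
    xf = cx + depth * np.tan(np.radians(tilt_x))
    inten = background * (1.0 + (peak - 1.0) * np.exp(
        -((Z - zf) ** 2) / (2 * sigma_z ** 2)
        - ((X - xf) ** 2 + (Y - cy) ** 2) / (2 * sigma_r ** 2)))
    return struct.astype(np.float32), inten.astype(np.float32)


class TestAnnotate:
    def test_straight_cylinder_axis_along_z(self):
        struct, inten = _gaussian_focus_volume()
        ann = annotate_axes(struct, inten, RES)
        angle = np.degrees(np.arccos(abs(ann.anatomical_axis[2])))
        assert angle < 0.5
        assert ann.distal_tip[2] == pytest.approx(6.0, abs=0.2)

    @pytest.mark.parametrize("tilt", [5.0, 10.0])
    def test_tilted_cylinder_axis_recovered(self, tilt):
        struct, inten = _gaussian_focus_volume(shape=(80, 60, 120), tilt_x=tilt)
        ann = annotate_axes(struct, inten, RES)
        angle = np.degrees(np.arccos(abs(ann.anatomical_axis[2])))
        assert angle == pytest.approx(tilt, abs=1.0)

    def test_equal_centers_weighting_degenerate(self):
        """Rings with identical centers but varying area give the same axis
        as unweighted fitting (collinear centers)."""
        rings = [{"z": z, "center": (3.0, 3.0), "area_um2": a}
                 for z, a in zip(np.linspace(2, 6, 9), np.linspace(5, 1, 9))]
        struct, inten = _gaussian_focus_volume()
        ann = annotate_axes(struct, inten, RES, hints={"rings": rings})
        np.testing.assert_allclose(ann.anatomical_axis, [0, 0, 1], atol=1e-9)

    def test_constant_structure_fails(self):
        struct = np.zeros((20, 20, 40), np.float32)
        with pytest.raises(ValueError, match="annotation|constant"):
            annotate_axes(struct, struct + 1.0, RES)


class TestProfileAndFocus:
    def test_uniform_intensity_gives_unity_factor(self):
        struct, _ = _gaussian_focus_volume()
        inten = np.full_like(struct, 2.5) + struct * 1e-6
        ann = annotate_axes(struct, _gaussian_focus_volume()[1], RES)
        prof = concentration_profile(inten, 2.5, ann)
        np.testing.assert_allclose(prof.factor, 1.0, rtol=1e-5)
        assert find_focus(prof).no_focus

    def test_gaussian_peak_recovered(self):
        struct, inten = _gaussian_focus_volume(peak=6.6, depth=5.8, sigma_r=0.5)
        ann = annotate_axes(struct, inten, RES)
        prof = concentration_profile(inten, 1.0, ann)
        focus = find_focus(prof)
        # closed form: disk average of the radial Gaussian over the 0.75-um
        # profile cylinder
        R, sr = 0.75, 0.5
        disk_avg = (2 * sr ** 2 / R ** 2) * (1 - np.exp(-R ** 2 / (2 * sr ** 2)))
        assert focus.peak_factor == pytest.approx(1 + 5.6 * disk_avg, rel=0.03)
        assert focus.focal_length == pytest.approx(5.8, abs=1.5 / RES)
        assert not focus.truncated

    def test_normalization_invariance(self):
        struct, inten = _gaussian_focus_volume()
        ann = annotate_axes(struct, inten, RES)
        p1 = concentration_profile(inten, 2.0, ann)
        p2 = concentration_profile(inten * 7.0, 14.0, ann)
        np.testing.assert_allclose(p1.factor, p2.factor, rtol=1e-6)

    def test_truncated_peak_flagged(self):
        # focus just past the distal boundary: the profile rises to the edge
        struct, inten = _gaussian_focus_volume(depth=6.5)
        ann = annotate_axes(struct, inten, RES,
                            hints={"peak_point": (3.0, 3.0, 11.9)})
        prof = concentration_profile(inten, 1.0, ann)
        focus = find_focus(prof)
        assert focus.truncated

    def test_tie_breaks_proximal(self):
        from mitolens.focusing_metrics import ConcentrationProfile
        depth = np.linspace(0, 10, 51)
        factor = np.ones_like(depth)
        factor[np.searchsorted(depth, 4.0)] = 5.0
        factor[np.searchsorted(depth, 8.0)] = 5.0
        prof = ConcentrationProfile(depth=depth, factor=factor, halo_depth=-2)
        assert find_focus(prof).focal_length == pytest.approx(4.0, abs=0.11)

    def test_radius_zero_limit_converges_to_axis_line(self):
        struct, inten = _gaussian_focus_volume()
        ann = annotate_axes(struct, inten, RES)
        wide = concentration_profile(inten, 1.0, ann, radius=0.75)
        narrow = concentration_profile(inten, 1.0, ann, radius=0.08)
        k = np.argmin(np.abs(narrow.depth - 5.8))
        # the narrow cylinder approaches the on-axis value (the peak)
        assert narrow.factor[k] > wide.factor[np.argmin(np.abs(wide.depth - 5.8))]
        assert narrow.factor[k] == pytest.approx(6.6, rel=0.02)


class TestOsr:
    def test_uniform_volume_unity(self):
        vol = np.full((40, 40, 100), 3.0, np.float32)
        f = osr_concentration(vol, 3.0, tip=(2, 2, 2), axis_dir=(0, 0, 1),
                              resolution=RES)
        assert f == pytest.approx(1.0)

    def test_centered_focus_mean_recovered(self):
        """OSR mean over the cylinder matches a direct numerical integral."""
        struct, inten = _gaussian_focus_volume(peak=6.6, depth=3.0)
        tip = np.array([3.0, 3.0, 6.0])
        f = osr_concentration(inten, 1.0, tip, (0, 0, 1), RES)
        # independent oracle: dense-grid integral of the same Gaussian
        x = np.linspace(-0.75, 0.75, 101)
        xx, yy = np.meshgrid(x, x, indexing="ij")
        disk = xx ** 2 + yy ** 2 <= 0.75 ** 2
        z = np.linspace(0, 6.0, 301)
        vals = []
        for zi in z:
            g = 1.0 + 5.6 * np.exp(-((zi - 3.0) ** 2) / 2.0
                                   - (xx ** 2 + yy ** 2) / (2 * 0.25))
            vals.append(g[disk].mean())
        expected = np.mean(vals)
        assert f == pytest.approx(expected, rel=0.02)

    def test_tilted_axis_loses_focus(self):
        struct, inten = _gaussian_focus_volume(peak=6.6, depth=3.0)
        tip = np.array([3.0, 3.0, 6.0])
        aligned = osr_concentration(inten, 1.0, tip, (0, 0, 1), RES)
        tilted = osr_concentration(inten, 1.0, tip,
                                   (np.sin(np.radians(10)), 0,
                                    np.cos(np.radians(10))), RES)
        assert tilted < aligned

    def test_cylinder_outside_volume_rejected(self):
        vol = np.ones((20, 20, 40), np.float32)
        with pytest.raises(ValueError, match="outside"):
            osr_concentration(vol, 1.0, tip=(50, 50, 50), axis_dir=(0, 0, 1),
                              resolution=RES)


class TestStackIO:
    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        vol = rng.random((15, 12, 30)).astype(np.float32)
        path = tmp_path / "stack.tif"
        write_stack(path, vol, resolution=16.0, origin=(0, 0, 0))
        back, res, origin = read_stack(path)
        np.testing.assert_array_equal(back, vol)
        assert res == 16.0

    def test_2d_volume_round_trip(self, tmp_path):
        vol = np.arange(50, dtype=np.float32).reshape(5, 10)
        path = tmp_path / "stack2d.tif"
        write_stack(path, vol, resolution=25.0)
        back, res, _ = read_stack(path)
        assert back.shape == (5, 1, 10)
        np.testing.assert_array_equal(back[:, 0, :], vol)
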