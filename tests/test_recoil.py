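import math

import numpy as np
import pytest
from scipy import ndimage

import folliquant as fq
from folliquant.model import GeometryError, ValidationError
from folliquant.recoil import RecoilResult, VelocityField
from folliquant.synthetic import (_render_fiber_frame, default_manifest,
                                  load_fixture, resolve_cut_segments)
from numpy.random import default_rng


@pytest.fixture(scope="module")
def texture():
    """Noise-free fiber texture for shift-recovery tests."""
    m = load_fixture("ablation_control_cell_APcut")
    canvas, *_ = _render_fiber_frame(m, default_rng(0))
    return canvas


def _uniform_field(vx, vy, cal, n=9, spacing=16.0, center=80.0):
    g = np.arange(n) * spacing + center - spacing * (n - 1) / 2
    gx, gy = np.meshgrid(g, g)
    shape = gx.shape
    return VelocityField(gx, gy, np.full(shape, vx), np.full(shape, vy),
                         np.ones(shape), np.ones(shape, dtype=bool), 32, cal)


class TestPIVCore:
    def test_integer_shift_recovered_exactly(self, texture):
        cal = fq.Calibration(0.2, 2.0)
        post = np.roll(texture, (0, 3), axis=(0, 1))
        fld = fq.piv_displacement_field(texture, post, cal)
        dx = fld.vx / (cal.pixel_size / cal.frame_interval)
        dy = fld.vy / (cal.pixel_size / cal.frame_interval)
        inner = np.zeros(dx.shape, dtype=bool)
        inner[1:-1, 1:-1] = True
        sel = fld.valid & inner
        assert np.abs(dx[sel] - 3.0).max() <= 0.05
        assert np.abs(dy[sel]).max() <= 0.05

    @pytest.mark.parametrize("shift", [(0.5, 0.0), (0.0, 0.5), (0.3, -0.4)])
    def test_subpixel_shift_within_fifth_of_pixel(self, texture, shift):
        cal = fq.Calibration(0.2, 2.0)
        post = ndimage.shift(texture, (shift[1], shift[0]), order=3,
                             mode="nearest")
        fld = fq.piv_displacement_field(texture, post, cal)
        scale = cal.pixel_size / cal.frame_interval
        inner = np.zeros(fld.vx.shape, dtype=bool)
        inner[1:-1, 1:-1] = True
        sel = fld.valid & inner
        assert np.abs(fld.vx[sel] / scale - shift[0]).max() <= 0.2
        assert np.abs(fld.vy[sel] / scale - shift[1]).max() <= 0.2

    def test_identical_frames_zero_field(self, texture):
        fld = fq.piv_displacement_field(texture, texture,
                                        fq.Calibration(0.2, 2.0))
        assert np.abs(fld.vx[fld.valid]).max() == pytest.approx(0.0, abs=1e-9)
        assert np.abs(fld.vy[fld.valid]).max() == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("kw", [dict(window=8), dict(window=500),
                                    dict(overlap=1.0)])
    def test_bad_parameters_rejected(self, texture, kw):
        with pytest.raises(ValidationError):
            fq.piv_displacement_field(texture, texture,
                                      fq.Calibration(0.2, 2.0), **kw)


class TestFilterVectors:
    def test_single_outlier_invalidated(self, cal02):
        fld = _uniform_field(0.5, 0.0, cal02)
        fld.vx[4, 4] = 5.0
        out = fq.filter_vectors(fld)
        assert not out.valid[4, 4]
        assert out.valid.sum() == fld.valid.size - 1

    def test_clean_field_untouched(self, cal02):
        out = fq.filter_vectors(_uniform_field(0.3, -0.2, cal02))
        assert out.valid.all()

    def test_matches_bruteforce_median_test(self, cal02, rng):
        fld = _uniform_field(0.0, 0.0, cal02, n=7)
        fld.vx += rng.normal(0, 0.05, fld.vx.shape)
        fld.vy += rng.normal(0, 0.05, fld.vy.shape)
        fld.vx[2, 3] += 1.0
        fld.vy[5, 1] -= 1.0
        out = fq.filter_vectors(fld, median_threshold=2.0, eps_umps=0.01)
        # oracle: evaluate the normalised-median residual per vector
        ny, nx = fld.vx.shape
        expect = np.ones((ny, nx), dtype=bool)
        for i in range(ny):
            for j in range(nx):
                rs = []
                for comp in (fld.vx, fld.vy):
                    neigh = [comp[i + di, j + dj]
                             for di in (-1, 0, 1) for dj in (-1, 0, 1)
                             if not (di == dj == 0)
                             and 0 <= i + di < ny and 0 <= j + dj < nx]
                    med = np.median(neigh)
                    res = np.median(np.abs(np.asarray(neigh) - med))
                    rs.append(abs(comp[i, j] - med) / (res + 0.01))
                expect[i, j] = max(rs) <= 2.0
        assert np.array_equal(out.valid, expect)

    def test_all_invalid_warns(self, cal02):
        fld = _uniform_field(0.0, 0.0, cal02, n=3)
        fld.quality[:] = 0.0
        with pytest.warns(UserWarning, match="invalid"):
            fq.filter_vectors(fld)


class TestMaxRecoilSpeed:
    def test_uniform_recoil_arithmetic(self):
        # 3 px over 2 s at 0.2 um/px = 0.3 um/s away from the cut
        cal = fq.Calibration(0.2, 2.0)
        cut = fq.Polyline([[20.0, 80.0], [140.0, 80.0]], role="cut_line")
        fld = _uniform_field(0.0, 0.3, cal, n=9, spacing=12.0, center=80.0)
        above = fld.y < 80.0
        fld.vy[above] = -0.3
        res = fq.max_recoil_speed(fld, cut)
        assert res.max_recoil_speed == pytest.approx(0.3)
        assert res.side_speeds[1] == pytest.approx(0.3)
        assert res.side_speeds[-1] == pytest.approx(0.3)

    def test_fixture_recovery_single_seed(self):
        m = load_fixture("ablation_control_cell_APcut")
        stack, _, _ = fq.generate_ablation_pair(m)
        res = fq.measure_recoil(stack, resolve_cut_segments(m))
        assert res.max_recoil_speed == pytest.approx(m.recoil_vmax, rel=0.15)

    def test_rotation_invariance_five_angles(self):
        from skimage.transform import rotate
        m = load_fixture("ablation_control_cell_APcut").replace(
            n_cells_ap=5, n_cells_dv=5)
        stack, _, _ = fq.generate_ablation_pair(m)
        segs = resolve_cut_segments(m)
        base = fq.measure_recoil(stack, segs).max_recoil_speed
        h, w = stack.shape[1:]
        c = np.array([(w - 1) / 2, (h - 1) / 2])
        for deg in (10, 37, 90, 145, 230):
            th = math.radians(deg)
            R = np.array([[math.cos(th), math.sin(th)],
                          [-math.sin(th), math.cos(th)]])
            pre = rotate(stack.frame(0), deg, resize=False, order=3,
                         center=tuple(c))
            post = rotate(stack.frame(1), deg, resize=False, order=3,
                          center=tuple(c))
            rot_stack = fq.ImageStack(np.stack([np.clip(pre, 0, None),
                                                np.clip(post, 0, None)]),
                                      stack.calibration)
            # skimage rotates the image content by +deg counterclockwise
            # in display convention, i.e. by -deg in (x, y-down) coords
            verts = (segs[0].vertices - c) @ R.T + c
            cut = fq.Polyline(verts, role="cut_line")
            speed = fq.measure_recoil(rot_stack, cut).max_recoil_speed
            assert speed == pytest.approx(base, rel=0.10)

    def test_segmented_cut_uses_flanking_bands_only(self, cal02):
        cal = fq.Calibration(0.2, 2.0)
        segs = [fq.Polyline([[10.0, 80.0], [60.0, 80.0]], role="cut_line"),
                fq.Polyline([[100.0, 80.0], [150.0, 80.0]], role="cut_line")]
        fld = _uniform_field(0.0, 0.3, cal, n=11, spacing=14.0, center=80.0)
        fld.vy[fld.y < 80.0] = -0.3
        res = fq.max_recoil_speed(fld, segs)
        # vectors over the gap (60 < x < 100, away from both segments'
        # perpendicular bands) must not be counted
        assert res.n_vectors < fld.valid.sum()
        assert res.max_recoil_speed == pytest.approx(0.3)

    def test_no_vectors_in_band_rejected(self, cal02):
        fld = _uniform_field(0.1, 0.0, fq.Calibration(0.2, 2.0), n=3,
                             spacing=4.0, center=10.0)
        cut = fq.Polyline([[200.0, 200.0], [240.0, 200.0]], role="cut_line")
        with pytest.raises(GeometryError):
            fq.max_recoil_speed(fld, cut)


class TestAnisotropyRatio:
    def test_printed_speeds_give_twenty_two(self):
        a = RecoilResult(max_recoil_speed=0.22)
        b = RecoilResult(max_recoil_speed=0.01)
        assert fq.anisotropy_ratio(a, b) == pytest.approx(22.0)

    def test_equal_speeds_give_one(self):
        assert fq.anisotropy_ratio(0.13, 0.13) == pytest.approx(1.0)

    def test_reciprocity(self):
        assert (fq.anisotropy_ratio(0.76, 0.22)
                * fq.anisotropy_ratio(0.22, 0.76)) == pytest.approx(1.0)

    def test_zero_denominator_undefined(self):
        assert math.isnan(fq.anisotropy_ratio(0.2, 0.0))


class TestKymograph:
    def test_static_movie_identical_columns(self, cal02, rng):
        img = rng.uniform(0, 100, (40, 60))
        stack = fq.ImageStack(np.stack([img] * 5), cal02)
        line = fq.Polyline([[5.0, 20.0], [55.0, 20.0]], role="kymograph_line")
        k = fq.kymograph(stack, line)
        assert k.shape[1] == 5
        for t in range(1, 5):
            assert np.allclose(k[:, t], k[:, 0])

    def test_single_frame_one_column(self, cal02):
        stack = fq.ImageStack(np.ones((1, 30, 30)), cal02)
        line = fq.Polyline([[2.0, 15.0], [28.0, 15.0]], role="kymograph_line")
        assert fq.kymograph(stack, line).shape[1] == 1

    def test_moving_feature_slopes_at_its_speed(self, cal02):
        # bright spot advancing 2 px/frame makes a streak of slope 2
        n_t, w = 8, 80
        data = np.zeros((n_t, 20, w))
        for t in range(n_t):
            data[t, :, 10 + 2 * t] = 100.0
        stack = fq.ImageStack(data, cal02)
        line = fq.Polyline([[0.0, 10.0], [float(w - 1), 10.0]],
                           role="kymograph_line")
        k = fq.kymograph(stack, line)
        peaks = k.argmax(axis=0)
        assert np.allclose(np.diff(peaks), 2.0)

    def test_line_outside_image_rejected(self, cal02):
        stack = fq.ImageStack(np.ones((1, 30, 30)), cal02)
        with pytest.raises(GeometryError):
            fq.kymograph(stack, fq.Polyline([[0.0, 0.0], [99.0, 0.0]],
                                            role="kymograph_line"))
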