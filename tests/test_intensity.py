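import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import folliquant as fq
from folliquant.model import ValidationError
from folliquant.synthetic import default_manifest


def _uniform_stack(value, cal, shape=(1, 20, 40)):
    return fq.ImageStack(np.full(shape, float(value)), cal)


def _rect_mask(h=20, w=40):
    lab = np.zeros((h, w), dtype=int)
    lab[2:18, 0:40] = 1
    return fq.LabelMask(lab)


class TestBackgroundSubtraction:
    def test_constant_offset_removed(self, cal02):
        stack = _uniform_stack(100, cal02)
        bg = np.zeros((20, 40), dtype=bool)
        bg[:2] = True
        stack.data[:, :2] = 10.0
        out = fq.subtract_background(stack, bg)
        assert np.allclose(out.data[:, 2:], 90.0)

    def test_image_equal_to_background_goes_to_zero(self, cal02):
        stack = _uniform_stack(55, cal02)
        out = fq.subtract_background(stack, np.ones((20, 40), dtype=bool))
        assert np.all(out.data == 0.0)

    def test_per_frame_offsets_independent(self, cal02, rng):
        # oracle: subtract each frame's own background mean directly
        data = rng.uniform(50, 150, (2, 20, 40))
        bg = np.zeros((20, 40), dtype=bool)
        bg[:3] = True
        stack = fq.ImageStack(data, cal02)
        out = fq.subtract_background(stack, bg)
        for t in range(2):
            expected = np.clip(data[t] - data[t][bg].mean(), 0, None)
            assert np.allclose(out.data[t], expected)

    def test_empty_background_rejected(self, cal02):
        with pytest.raises(ValidationError):
            fq.subtract_background(_uniform_stack(1, cal02),
                                   np.zeros((20, 40), dtype=bool))


class TestBleachCorrection:
    def test_recovers_tau_and_flattens(self, cal02, rng):
        cal = fq.Calibration(0.2, frame_interval=10.0)
        t = np.arange(60) * 10.0
        tau = 300.0
        base = rng.uniform(80, 120, (20, 30))
        data = base[None] * np.exp(-t / tau)[:, None, None]
        corr, fit = fq.correct_bleaching(fq.ImageStack(data, cal))
        assert fit.corrected
        assert fit.tau == pytest.approx(tau, rel=0.05)
        means = corr.data.mean(axis=(1, 2))
        assert np.ptp(means) / means.mean() < 0.02

    def test_constant_movie_left_untouched(self, cal02):
        stack = _uniform_stack(70, cal02, (6, 10, 10))
        out, fit = fq.correct_bleaching(stack)
        assert not fit.corrected and math.isinf(fit.tau)
        assert np.array_equal(out.data, stack.data)

    def test_oscillation_preserved_on_flat_field(self):
        # single oscillating cell on a non-bleaching background: the
        # field-level fit sees no net decay and must not distort the cycle
        cal = fq.Calibration(0.2, frame_interval=30.0)
        t = np.arange(60) * 30.0
        data = np.full((60, 20, 20), 100.0)
        osc = 20 * np.sin(2 * np.pi * t / 360.0)
        data[:, 5:10, 5:10] += osc[:, None, None]
        corr, fit = fq.correct_bleaching(fq.ImageStack(data, cal))
        trace = corr.data[:, 5:10, 5:10].mean(axis=(1, 2))
        amp_in = 0.5 * np.ptp(data[:, 5:10, 5:10].mean(axis=(1, 2)))
        amp_out = 0.5 * np.ptp(trace)
        assert amp_out == pytest.approx(amp_in, rel=0.05)

    def test_reapplying_decay_restores_input(self, cal02, rng):
        cal = fq.Calibration(0.2, frame_interval=10.0)
        t = np.arange(40) * 10.0
        data = rng.uniform(50, 100, (40, 8, 8)) * np.exp(-t / 200.0)[:, None, None]
        stack = fq.ImageStack(data, cal)
        corr, fit = fq.correct_bleaching(stack)
        redone = corr.data * np.exp(-t / fit.tau)[:, None, None]
        assert np.allclose(redone, data, rtol=1e-10)

    def test_too_few_frames_rejected(self, cal02):
        with pytest.raises(ValidationError):
            fq.correct_bleaching(_uniform_stack(1, cal02, (3, 8, 8)))


class TestPartition:
    def test_rectangle_splits_20_10_10(self, cal02):
        mask = _rect_mask()
        part = fq.partition_cell(mask, 1, cal02)
        xs_c = np.unique(np.nonzero(part.central_mask)[1])
        assert part.central_mask.sum() == 20 * 16
        assert part.lateral_mask.sum() == 20 * 16
        assert xs_c.min() == 10 and xs_c.max() == 29

    @given(st.integers(0, 10 ** 6))
    @settings(max_examples=25, deadline=None)
    def test_masks_tile_cell_exactly(self, seed):
        rng = np.random.default_rng(seed)
        lab = np.zeros((24, 24), dtype=int)
        y, x = rng.integers(0, 12, 2)
        h, w = rng.integers(6, 12, 2)
        lab[y:y + h, x:x + w] = 1
        mask = fq.LabelMask(lab)
        part = fq.partition_cell(mask, 1, fq.Calibration(0.2))
        union = part.central_mask | part.lateral_mask
        assert np.array_equal(union, mask.cell_mask(1))
        assert not (part.central_mask & part.lateral_mask).any()

    def test_rotated_frame_matches_rotate_then_partition(self):
        # oracle: a rectangle rotated by 30 deg analysed with
        # axis_frame=30 deg must split like the axis-aligned original
        import skimage.transform as tf
        lab = np.zeros((80, 80), dtype=np.float64)
        lab[30:50, 10:70] = 1.0
        rot = tf.rotate(lab, -30, resize=False, order=0, center=(40, 40))
        mask_rot = fq.LabelMask((rot > 0.5).astype(int))
        cal_rot = fq.Calibration(0.2, axis_frame=math.radians(30))
        part = fq.partition_cell(mask_rot, 1, cal_rot)
        area = mask_rot.cell_mask(1).sum()
        assert part.central_mask.sum() == pytest.approx(area / 2, rel=0.06)

    def test_tiny_cell_rejected(self, cal02):
        lab = np.zeros((10, 10), dtype=int)
        lab[2:8, 4:6] = 1  # 2 px along AP
        with pytest.raises(ValidationError):
            fq.partition_cell(fq.LabelMask(lab), 1, cal02)


class TestRatios:
    def test_uniform_cell_ratio_one(self, cal02):
        mask = _rect_mask()
        part = fq.partition_cell(mask, 1, cal02)
        r = fq.central_lateral_ratio(_uniform_stack(42, cal02), part)
        assert r[0] == pytest.approx(1.0)

    def test_zero_lateral_flagged_nan(self, cal02):
        mask = _rect_mask()
        part = fq.partition_cell(mask, 1, cal02)
        stack = _uniform_stack(0, cal02)
        stack.data[:, part.central_mask] = 10.0
        assert math.isnan(fq.central_lateral_ratio(stack, part)[0])

    def test_generator_central_fraction_recovered(self):
        # f = 0.75 on (nearly) equal-area bands gives ratio ~ 3
        m = default_manifest("fiber", n_cells_ap=6, n_cells_dv=4,
                             central_fraction=0.75, filopodia_per_cell=0,
                             noise_sigma=0.0, puncta_contrast=0.0)
        stack, mask, _, _ = fq.generate_fiber_scene(m)
        ratios = []
        for lab in mask.present_labels():
            part = fq.partition_cell(mask, int(lab), stack.calibration)
            ratios.append(fq.central_lateral_ratio(stack, part)[0])
        assert np.mean(ratios) == pytest.approx(3.0, rel=0.12)

    def test_scale_invariance(self, cal02, rng):
        mask = _rect_mask()
        part = fq.partition_cell(mask, 1, cal02)
        data = rng.uniform(10, 100, (1, 20, 40))
        r1 = fq.central_lateral_ratio(fq.ImageStack(data, cal02), part)
        r2 = fq.central_lateral_ratio(fq.ImageStack(7.3 * data, cal02), part)
        assert r1[0] == pytest.approx(r2[0])


class TestCloneRelative:
    def _two_cell_stack(self, clone_val, wt_val, cal):
        lab = np.zeros((10, 20), dtype=int)
        lab[:, :10] = 1
        lab[:, 10:] = 2
        data = np.zeros((1, 10, 20))
        data[:, :, :10] = clone_val
        data[:, :, 10:] = wt_val
        return fq.ImageStack(data, cal), fq.LabelMask(lab, frozenset({1}))

    def test_half_intensity_gives_half_ratio(self, cal02):
        stack, mask = self._two_cell_stack(50, 100, cal02)
        r = fq.clone_relative_intensity(stack, mask)
        assert r[1][0] == pytest.approx(0.5)

    def test_equal_statistics_give_unity(self, cal02):
        stack, mask = self._two_cell_stack(80, 80, cal02)
        assert fq.clone_relative_intensity(stack, mask)[1][0] == pytest.approx(1.0)

    def test_generator_clone_scale_recovered(self):
        m = default_manifest("fiber", n_cells_ap=5, n_cells_dv=4,
                             clone_labels=[7, 8, 12], clone_intensity_scale=0.6,
                             filopodia_per_cell=0, noise_sigma=0.02)
        stack, mask, _, _ = fq.generate_fiber_scene(m)
        r = fq.clone_relative_intensity(stack, mask)
        vals = [v[0] for v in r.values()]
        assert np.mean(vals) == pytest.approx(0.6, abs=0.06)

    def test_no_wild_type_rejected(self, cal02):
        lab = np.ones((8, 8), dtype=int)
        mask = fq.LabelMask(lab, frozenset({1}))
        with pytest.raises(ValidationError):
            fq.clone_relative_intensity(_uniform_stack(5, cal02, (1, 8, 8)), mask)

    def test_rescaling_invariance(self, cal02):
        stack, mask = self._two_cell_stack(60, 90, cal02)
        r1 = fq.clone_relative_intensity(stack, mask)[1][0]
        r2 = fq.clone_relative_intensity(stack.with_data(stack.data * 3.7),
                                         mask)[1][0]
        assert r1 == pytest.approx(r2)
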