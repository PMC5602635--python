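"""Optical thresholding: areas, volumes, curves, threshold selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from thrombovol.synthetic import make_thrombus_field, render_zstack
from thrombovol.volumetry import (
    ImagePlane,
    ThresholdCurves,
    ZStack,
    analyze_stack,
    select_optimal_threshold,
    sensitivity_analysis,
    stack_height,
    threshold_curves,
    thresholded_area,
    volume_ot,
    volume_uncertainty,
)

F = 0.33


def plane(arr, f=F):
    return ImagePlane(np.asarray(arr, dtype=np.uint8), f)


class TestThresholdedArea:
    def test_full_sensor_investigation_area(self):
        """A fully lit 512x512 sensor at 0.33 µm/px covers 28547.48 µm²."""
        p = plane(np.full((512, 512), 255))
        assert thresholded_area(p, 1) == pytest.approx(28547.4816, abs=1e-6)

    def test_empty_plane(self):
        assert thresholded_area(plane(np.zeros((16, 16))), 1) == 0.0

    def test_threshold_zero_counts_everything(self):
        p = plane(np.zeros((7, 9)))
        assert thresholded_area(p, 0) == pytest.approx(7 * 9 * F**2)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pixel_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        arr = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        count = 0
        for r in range(16):
            for c in range(16):
                if arr[r, c] >= 128:
                    count += 1
        assert thresholded_area(plane(arr), 128) == pytest.approx(count * F**2)

    @pytest.mark.parametrize("thr", [-1, 256])
    def test_rejects_out_of_range_threshold(self, thr):
        with pytest.raises(ValueError):
            thresholded_area(plane(np.zeros((4, 4))), thr)


class TestVolumeOt:
    def test_uniform_stack_closed_form(self):
        stack = ZStack.from_array(
            np.full((10, 512, 512), 255, dtype=np.uint8), delta_z=0.5
        )
        assert volume_ot(stack, 1) == pytest.approx(10 * 0.5 * 28547.4816)

    def test_threshold_above_fmax_gives_zero(self):
        stack = ZStack.from_array(
            np.full((4, 8, 8), 100, dtype=np.uint8), delta_z=0.5
        )
        assert volume_ot(stack, 101) == 0.0

    def test_noiseless_pyramid_near_analytic(self):
        """Rendered square pyramid: V_OT within one z-slab plus one pixel
        shell of the analytic (1/3) base² height."""
        hmap, truth = make_thrombus_field(
            1, base_size=(60, 60), height=(20.0, 20.0), shapes=("pyramid",),
            seed=0, image_size=64,
        )
        stack, truth = render_zstack(
            hmap, truth, background_sd=0.0, signal_sd=0.0, seed=0
        )
        v = volume_ot(stack, 100)
        analytic = (60 * F) ** 2 * 20.0 / 3.0
        # slab quantization adds at most delta_z per covered pixel column,
        # the staircase boundary at most a one-pixel shell per slab
        slack = 0.5 * (hmap > 0).sum() * F**2 + 4 * 60 * F * F * 20.0
        assert abs(v - analytic) <= slack
        assert v == pytest.approx(truth.rendered_volume)

    def test_rejects_empty_stack(self):
        with pytest.raises(ValueError):
            ZStack(planes=())


@pytest.mark.parametrize(
    "n, dz, expect", [(87, 0.5, 43.0), (1, 0.7, 0.0), (11, 0.5, 5.0)]
)
def test_stack_height(n, dz, expect):
    assert stack_height(n, dz) == pytest.approx(expect)


def test_stack_height_rejects_empty():
    with pytest.raises(ValueError):
        stack_height(0, 0.5)


class TestThresholdCurves:
    def test_binary_stack_constant_then_drop(self):
        arr = np.zeros((5, 16, 16), dtype=np.uint8)
        arr[:, 4:10, 4:10] = 200
        curves = threshold_curves(ZStack.from_array(arr, delta_z=0.5))
        v, h = curves.volume_curve, curves.height_curve
        assert np.all(v[1:201] == v[1])
        assert np.all(h[1:201] == 4 * 0.5)
        assert curves.thresholds[-1] == 200

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_per_threshold_oracle(self, seed):
        rng = np.random.default_rng(seed)
        arr = rng.integers(0, 60, (4, 12, 12)).astype(np.uint8)
        stack = ZStack.from_array(arr, delta_z=0.5)
        curves = threshold_curves(stack)
        for thr in curves.thresholds:
            assert curves.volume_curve[thr] == pytest.approx(volume_ot(stack, thr))
            # oracle: topmost plane with a surviving pixel, scanned directly
            h = 0.0
            for i in range(arr.shape[0]):
                if (arr[i] >= thr).any():
                    h = i * 0.5
            assert curves.height_curve[thr] == pytest.approx(h)

    @settings(max_examples=30, deadline=None)
    @given(
        hnp.arrays(
            np.uint8, st.tuples(st.integers(1, 4), st.integers(2, 6), st.integers(2, 6))
        )
    )
    def test_curves_non_increasing(self, arr):
        """Survival-count monotonicity: both curves non-increasing in Thr."""
        curves = threshold_curves(ZStack.from_array(arr))
        assert np.all(np.diff(curves.volume_curve) <= 1e-9)
        assert np.all(np.diff(curves.height_curve) <= 1e-9)

    def test_threshold_zero_counts_full_planes(self):
        arr = np.zeros((3, 8, 8), dtype=np.uint8)
        arr[0, 0, 0] = 5
        stack = ZStack.from_array(arr, delta_z=0.5)
        curves = threshold_curves(stack)
        assert curves.volume_curve[0] == pytest.approx(3 * 0.5 * 64 * F**2)


class TestSelectOptimalThreshold:
    def test_binary_stack_selects_object_intensity(self):
        arr = np.zeros((5, 16, 16), dtype=np.uint8)
        arr[:, 4:10, 4:10] = 200
        thr = select_optimal_threshold(threshold_curves(ZStack.from_array(arr)))
        assert thr == 200

    def test_empty_content_signalled(self):
        arr = np.zeros((3, 8, 8), dtype=np.uint8)
        arr[:, 2, 2] = 1  # F_max = 1 but only bottom-up planes... all planes lit
        arr[1:, :, :] = 0  # only the focal plane has content
        with pytest.raises(ValueError):
            select_optimal_threshold(
                threshold_curves(ZStack.from_array(arr))
            )

    def test_noisy_stack_recovers_rendered_volume_within_15pct(self):
        """End to end: auto threshold on a noisy pyramid stack lands just
        above the noise floor and recovers the rendered volume."""
        hmap, truth = make_thrombus_field(
            1, base_size=(60, 60), height=(20.0, 20.0), shapes=("pyramid",),
            seed=0,
        )
        stack, truth = render_zstack(hmap, truth, seed=0)
        est, _ = analyze_stack(stack)
        assert 200 > est.threshold_used > 8
        assert abs(est.value - truth.rendered_volume) <= 0.15 * truth.rendered_volume


class TestVolumeUncertainty:
    @staticmethod
    def _curves(volume):
        volume = np.asarray(volume, dtype=float)
        return ThresholdCurves(
            thresholds=np.arange(len(volume)),
            volume_curve=volume,
            height_curve=np.zeros(len(volume)),
            delta_z=0.5,
        )

    def test_linear_curve_closed_form(self):
        """Locally linear V(Thr) with slope -s and V = 1: u = s·sqrt(3)."""
        s = 0.02
        v = 1.0 + s * (5 - np.arange(11))
        u = volume_uncertainty(self._curves(v), thr=5, delta_thr=3)
        assert u == pytest.approx(s * np.sqrt(3.0) / 1.0)

    def test_flat_curve_zero_uncertainty(self):
        assert volume_uncertainty(self._curves(np.ones(9)), 4) == 0.0

    def test_boundary_falls_back_to_one_sided(self):
        v = np.array([4.0, 3.0, 2.0])
        assert volume_uncertainty(self._curves(v), 0) == pytest.approx(
            np.sqrt(3.0) / 4.0
        )
        assert volume_uncertainty(self._curves(v), 2) == pytest.approx(
            np.sqrt(3.0) / 2.0
        )

    def test_low_contrast_stack_lands_in_band(self):
        """On a dim stack whose object intensities sit just above the selected
        threshold, the propagated uncertainty is in the 10-25% range — the
        regime real stacks show (order of 15%)."""
        hmap, truth = make_thrombus_field(
            3, base_size=(80, 120), height=(10.0, 20.0), seed=1
        )
        stack, _ = render_zstack(
            hmap, truth, object_intensity=35, signal_sd=4.0, seed=1
        )
        est, _ = analyze_stack(stack)
        assert 0.10 <= est.relative_uncertainty <= 0.25


@pytest.fixture(scope="module")
def noisy_stack():
    hmap, truth = make_thrombus_field(
        2, base_size=(40, 60), height=(8.0, 15.0), seed=2, image_size=128
    )
    stack, _ = render_zstack(hmap, truth, seed=2)
    return stack


class TestSensitivityAnalysis:
    def test_zero_offset_is_exactly_zero(self, noisy_stack):
        dv = sensitivity_analysis(noisy_stack, 30, halfwidth=3)
        assert dv[3] == 0.0

    def test_plateau_stack_flat_everywhere(self):
        arr = np.zeros((4, 16, 16), dtype=np.uint8)
        arr[:, 2:12, 2:12] = 200
        dv = sensitivity_analysis(ZStack.from_array(arr), 100, halfwidth=10)
        assert np.all(dv == 0.0)

    def test_matches_per_offset_recomputation(self, noisy_stack):
        thr, hw = 30, 5
        dv = sensitivity_analysis(noisy_stack, thr, halfwidth=hw)
        v0 = volume_ot(noisy_stack, thr)
        for i in range(-hw, hw + 1):
            expect = 100.0 * (volume_ot(noisy_stack, thr + i) - v0) / v0
            if i == 0:
                expect = 0.0
            assert dv[i + hw] == pytest.approx(expect)

    def test_non_increasing_in_threshold(self, noisy_stack):
        dv = sensitivity_analysis(noisy_stack, 30, halfwidth=8)
        assert np.all(np.diff(dv) <= 1e-9)

    def test_rejects_zero_reference_volume(self):
        arr = np.zeros((2, 8, 8), dtype=np.uint8)
        arr[:, 1, 1] = 10
        with pytest.raises(ValueError):
            sensitivity_analysis(ZStack.from_array(arr), 50, halfwidth=10)


def test_wide_dtype_input_rescaled_with_warning():
    arr = np.linspace(0, 4000, 64, dtype=np.uint16).reshape(8, 8)
    with pytest.warns(UserWarning, match="rescaling"):
        p = ImagePlane(arr)
    assert p.intensities.max() == 255
    assert p.intensities.dtype == np.uint8
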