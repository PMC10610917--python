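"""Tests for two-point calibration, temperature windowing and target cropping."""

import numpy as np
import pytest

from pfseg.calibration import (
    BlackbodyReference,
    CropFailureError,
    DegenerateCalibrationError,
    RadiometricFrame,
    Rect,
    TemperatureMap,
    WindowSpec,
    calibrate_two_point,
    crop_calibration_targets,
    grayscale_to_temperature,
    load_blackbody_sidecar,
    read_frame,
    read_mask,
    save_blackbody_sidecar,
    temperature_to_grayscale,
    write_frame,
    write_mask,
)
from pfseg.gamma import GrayscaleImage


def _frame_with_law(rng, slope, offset, shape=(40, 60)):
    """Counts drawn first; temperatures defined exactly by T = slope*c + offset."""
    counts = rng.integers(1000, 60000, size=shape).astype(np.uint16)
    counts[2:8, 2:8] = 30000     # low reference patch
    counts[2:8, 50:56] = 45000   # high reference patch
    t_true = slope * counts.astype(np.float64) + offset
    bb_low = BlackbodyReference(Rect(2, 8, 2, 8), slope * 30000 + offset)
    bb_high = BlackbodyReference(Rect(2, 8, 50, 56), slope * 45000 + offset)
    return RadiometricFrame(counts), t_true, bb_low, bb_high


class TestTwoPointCalibration:
    def test_recovers_generating_affine_law(self, rng):
        for slope, offset in [(5e-4, 10.0), (1.2e-3, -3.0)]:
            frame, t_true, lo, hi = _frame_with_law(rng, slope, offset)
            tmap = calibrate_two_point(frame, lo, hi)
            assert np.abs(tmap.temp_c - t_true).max() <= 1e-9

    def test_anchor_means_exact(self, rng):
        counts = rng.integers(0, 65535, size=(20, 30)).astype(np.uint16)
        counts[0:4, 0:4] = 20000
        counts[0:4, 26:30] = 40000
        counts[10, 10] = 20000  # equals the low-region mean
        counts[10, 11] = 30000  # exactly midway
        frame = RadiometricFrame(counts)
        lo = BlackbodyReference(Rect(0, 4, 0, 4), 28.0)
        hi = BlackbodyReference(Rect(0, 4, 26, 30), 36.0)
        tmap = calibrate_two_point(frame, lo, hi)
        assert tmap.temp_c[10, 10] == pytest.approx(28.0, abs=1e-9)
        assert tmap.temp_c[10, 11] == pytest.approx(32.0, abs=1e-9)

    def test_median_statistic_option(self, rng):
        counts = np.full((10, 10), 10000, dtype=np.uint16)
        counts[0:3, 0:3] = 20000
        counts[0, 0] = 60000  # outlier inside the reference patch
        counts[7:10, 7:10] = 40000
        frame = RadiometricFrame(counts)
        lo = BlackbodyReference(Rect(0, 3, 0, 3), 28.0)
        hi = BlackbodyReference(Rect(7, 10, 7, 10), 36.0)
        t_med = calibrate_two_point(frame, lo, hi, statistic="median")
        # median ignores the outlier: a 20000-count pixel reads exactly 28
        assert t_med.temp_c[1, 1] == pytest.approx(28.0, abs=1e-9)

    def test_degenerate_and_bounds_errors(self):
        counts = np.full((10, 10), 5000, dtype=np.uint16)
        frame = RadiometricFrame(counts)
        lo = BlackbodyReference(Rect(0, 2, 0, 2), 28.0)
        hi = BlackbodyReference(Rect(5, 7, 5, 7), 36.0)
        with pytest.raises(DegenerateCalibrationError):
            calibrate_two_point(frame, lo, hi)
        outside = BlackbodyReference(Rect(0, 2, 8, 12), 36.0)
        with pytest.raises(IndexError):
            calibrate_two_point(frame, lo, outside)


class TestTemperatureWindow:
    def test_center_maps_to_half(self):
        w = WindowSpec(center_c=32.0, width_c=10.0)
        img = temperature_to_grayscale(TemperatureMap(np.full((2, 2), 32.0)), w)
        assert np.all(img.values == 0.5)

    def test_clipping_at_edges(self):
        w = WindowSpec(center_c=32.0, width_c=10.0)
        t = TemperatureMap(np.array([[20.0, 27.0, 37.0, 45.0]]))
        v = temperature_to_grayscale(t, w).values[0]
        assert v[0] == 0.0 and v[1] == 0.0 and v[2] == 1.0 and v[3] == 1.0

    def test_linear_map_example(self):
        w = WindowSpec(center_c=30.0, width_c=10.0)
        img = temperature_to_grayscale(TemperatureMap(np.array([[28.0]])), w)
        assert img.values[0, 0] == pytest.approx(0.3)

    def test_order_preserving(self, rng):
        w = WindowSpec()
        t = np.sort(rng.uniform(20, 40, 100))
        v = temperature_to_grayscale(TemperatureMap(t[None, :]), w).values[0]
        assert np.all(np.diff(v) >= 0)

    def test_round_trip_inside_window(self, rng):
        w = WindowSpec(center_c=32.0, width_c=10.0)
        t = rng.uniform(w.low_c + 0.1, w.high_c - 0.1, (8, 8))
        img = temperature_to_grayscale(TemperatureMap(t), w)
        back = grayscale_to_temperature(img, w)
        assert np.abs(back.temp_c - t).max() < 1e-12
        again = temperature_to_grayscale(back, w)
        assert np.abs(again.values - img.values).max() < 1e-12


def _oracle_largest_empty(values_shape, regions):
    """Brute force over all pixel-aligned rectangles (small inputs only)."""
    h, w = values_shape
    blocked = np.zeros((h, w), dtype=bool)
    for r in regions:
        blocked[r.slices()] = True
    best = 0
    for r0 in range(h):
        for r1 in range(r0 + 1, h + 1):
            for c0 in range(w):
                for c1 in range(c0 + 1, w + 1):
                    if not blocked[r0:r1, c0:c1].any():
                        best = max(best, (r1 - r0) * (c1 - c0))
    return best


class TestCropCalibrationTargets:
    def test_margin_strips_leave_central_band(self, rng):
        img = GrayscaleImage(rng.uniform(0, 1, (40, 100)))
        regions = [Rect(5, 35, 0, 10), Rect(5, 35, 90, 100)]
        out = crop_calibration_targets(img, regions)
        assert out.shape == (40, 80)
        assert np.array_equal(out.values, img.values[:, 10:90])

    def test_empty_region_list_is_identity(self, rng):
        img = GrayscaleImage(rng.uniform(0, 1, (10, 10)))
        out = crop_calibration_targets(img, [])
        assert out is img

    def test_single_margin_strip(self, rng):
        img = GrayscaleImage(rng.uniform(0, 1, (20, 100)))
        out = crop_calibration_targets(img, [Rect(0, 20, 0, 10)])
        assert out.shape == (20, 90)

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(10):
            h, w = 9, 11
            regions = []
            for _ in range(rng.integers(1, 4)):
                r0 = int(rng.integers(0, h - 1)); c0 = int(rng.integers(0, w - 1))
                regions.append(Rect(r0, int(rng.integers(r0 + 1, h + 1)),
                                    c0, int(rng.integers(c0 + 1, w + 1))))
            img = GrayscaleImage(rng.uniform(0, 1, (h, w)))
            try:
                out = crop_calibration_targets(img, regions)
            except CropFailureError:
                assert _oracle_largest_empty((h, w), regions) == 0
                continue
            assert out.values.size == _oracle_largest_empty((h, w), regions)

    def test_full_coverage_raises(self):
        img = GrayscaleImage(np.zeros((4, 4)))
        with pytest.raises(CropFailureError):
            crop_calibration_targets(img, [Rect(0, 4, 0, 4)])

    def test_deterministic(self, rng):
        img = GrayscaleImage(rng.uniform(0, 1, (30, 30)))
        regions = [Rect(0, 10, 0, 10), Rect(20, 30, 20, 30)]
        a = crop_calibration_targets(img, regions)
        b = crop_calibration_targets(img, regions)
        assert np.array_equal(a.values, b.values)


class TestFileIO:
    @pytest.mark.parametrize("suffix", [".tif", ".png"])
    def test_frame_round_trip(self, tmp_path, rng, suffix):
        counts = rng.integers(0, 65535, size=(12, 16)).astype(np.uint16)
        frame = RadiometricFrame(counts)
        path = tmp_path / f"frame{suffix}"
        write_frame(path, frame)
        back = read_frame(path)
        assert np.array_equal(back.counts, counts)
        assert back.bit_depth == 16

    def test_mask_round_trip(self, tmp_path, rng):
        mask = rng.uniform(size=(10, 10)) > 0.5
        path = tmp_path / "mask.png"
        write_mask(path, mask)
        assert np.array_equal(read_mask(path), mask)

    def test_blackbody_sidecar_round_trip(self, tmp_path):
        refs = [
            BlackbodyReference(Rect(10, 90, 0, 12), 28.0),
            BlackbodyReference(Rect(10, 90, 148, 160), 36.0),
        ]
        path = tmp_path / "bb.json"
        save_blackbody_sidecar(path, refs)
        assert load_blackbody_sidecar(path) == refs
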