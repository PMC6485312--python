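"""Frame detection: convolution correctness, subgrid argmax, magnitude filter."""

import numpy as np
import pytest

from sarctrack.detect import (
    DetectionConfig,
    convolve_with_bank,
    filter_by_magnitude,
    select_grid_detections,
    subgrid_points,
)
from sarctrack.kernels import (
    WaveletShape,
    build_kernel_bank,
    make_single_wavelet,
)

SHAPE = WaveletShape(scale=1.5, stretch=3, wavelength=6, support=21)


def small_bank(p=3, q=2):
    return build_kernel_bank(SHAPE, 8, 14, p, q)


class TestConvolution:
    def test_self_match_response_is_one_and_maximal(self):
        bank = small_bank()
        k = bank.kernels[1][0]  # distance 11, angle 0
        frame = np.zeros((64, 64))
        frame[32 - 10 : 32 + 11, 32 - 10 : 32 + 11] = k.raster
        resp = convolve_with_bank(frame, bank)
        assert resp[1, 0, 32, 32] == pytest.approx(1.0, abs=1e-9)
        assert resp.max() == pytest.approx(1.0, abs=1e-9)

    def test_flat_frame_gives_zero_response(self):
        bank = small_bank()
        resp = convolve_with_bank(np.full((40, 40), 7.3), bank)
        assert np.all(np.abs(resp) < 1e-9)

    def test_matches_brute_force_dot_products(self):
        # spatial-domain oracle: sliding dot product with symmetric padding
        bank = small_bank()
        rng = np.random.default_rng(11)
        frame = rng.random((64, 64))
        resp = convolve_with_bank(frame, bank)
        s = SHAPE.support
        padded = np.pad(frame, s // 2, mode="symmetric")
        for _ in range(20):
            i = int(rng.integers(0, 64))
            j = int(rng.integers(0, 64))
            di = int(rng.integers(0, bank.n_distances))
            ai = int(rng.integers(0, bank.n_angles))
            direct = np.sum(
                padded[i : i + s, j : j + s] * bank.kernels[di][ai].raster
            )
            assert resp[di, ai, i, j] == pytest.approx(direct, abs=1e-8)

    def test_frame_smaller_than_support_rejected(self):
        with pytest.raises(ValueError, match="support"):
            convolve_with_bank(np.zeros((10, 10)), small_bank())

    def test_non_finite_frame_rejected(self):
        frame = np.zeros((40, 40))
        frame[3, 3] = np.nan
        with pytest.raises(ValueError):
            convolve_with_bank(frame, small_bank())


class TestGridSelection:
    def test_known_pair_recovered(self):
        # one synthetic sarcomere (spacing 11, angle 0) on a grid point
        bank = small_bank()
        cfg = DetectionConfig(hopsize=16, halfwindowsize=3)
        frame = np.zeros((64, 64))
        pair = make_single_wavelet(SHAPE, 0.0, 5.5) + make_single_wavelet(
            SHAPE, 0.0, -5.5
        )
        rows, cols = subgrid_points(frame.shape, cfg)
        r, c = rows[2], cols[2]  # interior grid point
        frame[r - 10 : r + 11, c - 10 : c + 11] = np.clip(pair, 0, None)
        resp = convolve_with_bank(frame, bank)
        dets = select_grid_detections(resp, bank, cfg)
        best = next(
            d for d in dets if d.grid_row == 2 and d.grid_col == 2
        )
        assert best.distance == pytest.approx(11.0)
        assert best.angle == pytest.approx(0.0)

    def test_matches_exhaustive_argmax(self):
        # independent brute-force selection over the response stack
        bank = small_bank()
        cfg = DetectionConfig(hopsize=12, halfwindowsize=4)
        rng = np.random.default_rng(3)
        frame = rng.random((64, 64))
        resp = convolve_with_bank(frame, bank)
        dets = select_grid_detections(resp, bank, cfg)
        rows, cols = subgrid_points(frame.shape, cfg)
        assert len(dets) == len(rows) * len(cols)
        for d in dets:
            r, c = rows[d.grid_row], cols[d.grid_col]
            best = (-np.inf, None)
            for di in range(bank.n_distances):
                for ai in range(bank.n_angles):
                    for i in range(max(0, r - 4), min(64, r + 5)):
                        for j in range(max(0, c - 4), min(64, c + 5)):
                            v = resp[di, ai, i, j]
                            if v > best[0]:
                                best = (v, (di, ai, i, j))
            di, ai, i, j = best[1]
            assert d.magnitude == pytest.approx(best[0])
            assert d.distance == bank.distances[di]
            assert d.angle == bank.angles[ai]
            assert d.location == (i, j)

    def test_zero_halfwindow_pins_location_to_grid(self):
        bank = small_bank()
        cfg = DetectionConfig(hopsize=12, halfwindowsize=0)
        rng = np.random.default_rng(5)
        resp = convolve_with_bank(rng.random((50, 50)), bank)
        dets = select_grid_detections(resp, bank, cfg)
        rows, cols = subgrid_points((50, 50), cfg)
        for d in dets:
            assert d.location == (rows[d.grid_row], cols[d.grid_col])

    def test_neighborhood_constraint_enforced(self):
        bank = small_bank()  # d_min = 8
        cfg = DetectionConfig(hopsize=4, halfwindowsize=8)
        with pytest.raises(ValueError, match="neighborhood"):
            select_grid_detections(np.zeros((2, 2, 40, 40)), bank, cfg)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            subgrid_points((0, 10), DetectionConfig(hopsize=10))


def _fake_detections(medians, border=None):
    """One-frame detection list with given magnitudes."""
    from sarctrack.detect import FrameDetection

    border = border or [False] * len(medians)
    return [
        [
            FrameDetection(i, 0, (0, 0), 10.0, 0.0, float(m), b)
            for i, (m, b) in enumerate(zip(medians, border))
        ]
    ]


class TestMagnitudeFilter:
    def test_quantile_zero_retains_all_interior(self):
        dets = _fake_detections([1.0, 5.0, 2.0])
        cfg = DetectionConfig(magnitude_quantile=0.0)
        assert filter_by_magnitude(dets, cfg) == [0, 1, 2]

    def test_bimodal_population_split(self):
        mags = [0.01, 0.02, 0.01, 9.0, 8.5, 9.2, 0.03, 8.8]
        dets = _fake_detections(mags)
        cfg = DetectionConfig(magnitude_quantile=0.5)
        kept = filter_by_magnitude(dets, cfg)
        assert kept == [3, 4, 5, 7]

    def test_single_frame_equals_plain_rule(self):
        mags = [1.0, 2.0, 3.0, 4.0]
        dets = _fake_detections(mags)
        cfg = DetectionConfig(magnitude_quantile=0.5)
        kept = filter_by_magnitude(dets, cfg)
        cutoff = np.quantile(mags, 0.5)
        assert kept == [i for i, m in enumerate(mags) if m >= cutoff]

    def test_identical_magnitudes_all_retained(self):
        dets = _fake_detections([2.0] * 5)
        cfg = DetectionConfig(magnitude_quantile=0.9)
        assert filter_by_magnitude(dets, cfg) == [0, 1, 2, 3, 4]

    def test_raising_quantile_is_monotone(self):
        rng = np.random.default_rng(0)
        dets = _fake_detections(list(rng.random(30)))
        prev = None
        for q in [0.0, 0.2, 0.4, 0.6, 0.8, 0.95]:
            kept = set(
                filter_by_magnitude(dets, DetectionConfig(magnitude_quantile=q))
            )
            if prev is not None:
                assert kept <= prev
            prev = kept

    def test_border_points_always_dropped(self):
        dets = _fake_detections([9.0, 1.0, 2.0], border=[True, False, False])
        cfg = DetectionConfig(magnitude_quantile=0.0)
        assert filter_by_magnitude(dets, cfg) == [1, 2]
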