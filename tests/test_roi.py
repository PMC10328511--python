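"""ΔF/F, circularity, morphology and SNR filters, low-pass pooling."""

import numpy as np
import pytest
from skimage import draw

from mismatch2p import roi


def brute_force_dff(f, window=1000, percentile=8.0):
    """Independent per-frame evaluation of the running-percentile ΔF/F."""
    f = np.asarray(f, float)
    n = len(f)
    half = window // 2
    f0 = np.empty(n)
    for i in range(n):
        lo = max(0, i - half + (1 - window % 2))
        hi = min(n, i + half + 1)
        f0[i] = np.percentile(f[lo:hi], percentile)
    return (f - f0) / np.median(f)


class TestComputeDff:
    def test_constant_trace_is_zero(self):
        d = roi.compute_dff(np.full(2000, 7.0), 60.0)
        np.testing.assert_allclose(d.values, 0.0, atol=1e-12)

    def test_boxcar_plateau_half(self):
        f = np.full(5000, 100.0)
        f[2000:2100] += 50.0
        d = roi.compute_dff(f, 60.0)
        assert np.median(d.values[2020:2080]) == pytest.approx(0.5, abs=0.01)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        f = 100.0 + rng.normal(0, 3, 3000).cumsum() * 0.01 + rng.uniform(0, 5, 3000)
        a = roi.compute_dff(f, 60.0).values
        b = roi.compute_dff(13.7 * f, 60.0).values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_drift_with_transients_baseline_near_zero(self):
        rng = np.random.default_rng(1)
        n = 6000
        f = 100.0 + 0.002 * np.arange(n)          # slow drift
        for i in rng.integers(500, n - 200, 8):   # sparse transients
            f[i:i + 60] += 40.0
        d = roi.compute_dff(f, 60.0)
        quiet = np.ones(n, bool)
        quiet[:300] = quiet[-300:] = False
        for i in np.flatnonzero(np.diff(f) > 5):
            quiet[max(0, i - 10): i + 120] = False
        assert np.abs(np.median(d.values[quiet])) < 0.02

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        f = 50.0 + rng.gamma(2.0, 2.0, 700)
        got = roi.compute_dff(f, 60.0, window=101).values
        np.testing.assert_allclose(got, brute_force_dff(f, window=101), atol=1e-10)

    def test_nonpositive_median_raises(self):
        with pytest.raises(ValueError):
            roi.compute_dff(np.full(100, -5.0), 60.0)


class TestCircularity:
    def test_disc_near_one(self):
        mask = np.zeros((60, 60), bool)
        rr, cc = draw.disk((30, 30), 20)
        mask[rr, cc] = True
        assert 0.9 <= roi.circularity_index(mask) <= 1.1

    def test_elongated_rectangle_small(self):
        mask = np.zeros((10, 160), bool)
        mask[3:6, 5:155] = True  # 3 x 150 px
        ci = roi.circularity_index(mask)
        assert ci == pytest.approx(4 * np.pi * 450 / roi.mask_perimeter(mask) ** 2)
        assert 0.05 < ci < 0.07

    def test_translation_invariance(self):
        mask = np.zeros((50, 50), bool)
        rr, cc = draw.ellipse(20, 20, 8, 14)
        mask[rr, cc] = True
        shifted = np.roll(np.roll(mask, 7, axis=0), -3, axis=1)
        assert roi.circularity_index(mask) == pytest.approx(
            roi.circularity_index(shifted), rel=1e-9)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            roi.circularity_index(np.zeros((5, 5), bool))


class TestMorphologyFilter:
    @pytest.mark.parametrize("ci,area,kept,reason", [
        (0.20, 500, False, "circularity"),
        (0.10, 100, False, "area"),
        (0.10, 450, True, ""),
    ])
    def test_threshold_logic(self, ci, area, kept, reason):
        g = roi.RoiGeometry(label=1, area=area, perimeter=10.0, circularity=ci)
        row = roi.morphology_filter([g]).iloc[0]
        assert row.kept == kept
        assert row.reasons == reason


class TestActivitySnr:
    def test_white_noise_excluded(self):
        rng = np.random.default_rng(3)
        snrs = []
        for _ in range(20):
            d = roi.DffTrace(rng.normal(0, 1, 6000), 60.0)
            snr, keep = roi.activity_snr(d)
            snrs.append(snr)
            assert not keep
        assert np.mean(snrs) == pytest.approx(1.0, abs=0.3)

    def test_slow_sinusoid_kept(self):
        t = np.arange(6000) / 60.0
        x = np.sin(2 * np.pi * 0.2 * t) + 0.01 * np.random.default_rng(0).normal(size=6000)
        snr, keep = roi.activity_snr(roi.DffTrace(x, 60.0))
        assert keep and snr > 100

    def test_zero_trace_excluded_with_reason(self):
        d = roi.DffTrace(np.zeros(6000), 60.0)
        snr, keep = roi.activity_snr(d)
        assert not keep and np.isnan(snr)
        assert d.qc["reasons"]

    def test_low_frame_rate_raises(self):
        with pytest.raises(ValueError, match="Nyquist"):
            roi.activity_snr(roi.DffTrace(np.random.default_rng(0).normal(size=800), 15.0))

    def test_keep_rates_on_noise_and_signal(self):
        rng = np.random.default_rng(4)
        t = np.arange(4800) / 60.0
        noise_kept = signal_kept = 0
        n = 200
        for i in range(n):
            pure = roi.DffTrace(rng.normal(0, 0.05, 4800), 60.0)
            noise_kept += roi.activity_snr(pure)[1]
            sig = 0.3 * np.sin(2 * np.pi * rng.uniform(0.1, 0.5) * t + rng.uniform(0, 6))
            bearing = roi.DffTrace(sig + rng.normal(0, 0.05, 4800), 60.0)
            signal_kept += roi.activity_snr(bearing)[1]
        assert noise_kept / n < 0.01
        assert signal_kept / n > 0.99


class TestLowpassAndPool:
    def test_single_roi_equals_filtered(self):
        rng = np.random.default_rng(5)
        d = roi.DffTrace(rng.normal(0, 1, 3000), 60.0)
        pooled = roi.lowpass_and_pool([d])
        np.testing.assert_allclose(pooled.values, roi.lowpass(d.values, 60.0))

    def test_two_identical_rois(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 3000)
        pooled = roi.lowpass_and_pool([roi.DffTrace(x, 60.0), roi.DffTrace(x.copy(), 60.0)])
        np.testing.assert_allclose(pooled.values, roi.lowpass(x, 60.0))

    def test_dc_unit_gain(self):
        d = roi.DffTrace(np.full(2000, 0.7), 60.0)
        np.testing.assert_allclose(roi.lowpass_and_pool([d]).values, 0.7, atol=1e-9)

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            roi.lowpass_and_pool([])

    def test_mixed_frame_rates_raise(self):
        with pytest.raises(ValueError):
            roi.lowpass_and_pool([roi.DffTrace(np.zeros(100), 60.0),
                                  roi.DffTrace(np.zeros(100), 30.0)])
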