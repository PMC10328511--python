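"""Trial responses, windows, visuomotor error, LMI, cell typing, density."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mismatch2p import responses, synth
from mismatch2p.responses import WindowSpec

FR = 60.0


class TestTrialResponse:
    spec = WindowSpec(baseline=(-1.0, 0.0), response=(0.66, 1.66))

    def test_constant_trace_zero(self):
        assert responses.trial_response(np.full(600, 0.3), FR, 5.0, self.spec) == 0.0

    def test_step_response(self):
        x = np.zeros(600)
        x[int(5.0 * FR):] = 0.4
        assert responses.trial_response(x, FR, 5.0, self.spec) == pytest.approx(0.4)

    def test_partial_boxcar_overlap_weighted(self):
        x = np.zeros(600)
        # 0.5 s boxcar of height 1 covering the first half second of the
        # 1 s response window -> overlap-weighted mean 0.5
        i0 = int((5.0 + 0.66) * FR)
        x[i0: i0 + int(0.5 * FR)] = 1.0
        assert responses.trial_response(x, FR, 5.0, self.spec) == pytest.approx(0.5, abs=0.02)

    def test_out_of_range_gives_nan(self):
        assert np.isnan(responses.trial_response(np.zeros(100), FR, 1.0, self.spec))

    def test_matrix_version_matches_scalar(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, (3, 1200))
        trig = [4.0, 9.0, 19.5]
        mat = responses.trial_response_matrix(x, FR, trig, self.spec)
        for i in range(3):
            for j, t in enumerate(trig):
                expected = responses.trial_response(x[i], FR, t, self.spec)
                if np.isnan(expected):
                    assert np.isnan(mat[i, j])
                else:
                    assert mat[i, j] == pytest.approx(expected)


class TestStandardWindows:
    @pytest.mark.parametrize("kind,dataset,response", [
        ("mismatch", "LC", (0.66, 1.66)),
        ("playback_halt", "LC", (0.66, 1.66)),
        ("flow_onset_open_loop", "LC", (1.06, 2.06)),
        ("stimulus", "V1", (0.33, 2.33)),
        ("flow_onset_replay", "V1", (0.73, 2.73)),
        ("locomotion_onset", "V1", (0.66, 4.0)),
    ])
    def test_window_table(self, kind, dataset, response):
        assert responses.standard_windows(kind, dataset).response == response

    def test_lc_locomotion_onset_baseline(self):
        spec = responses.standard_windows("locomotion_onset", "LC")
        assert spec.baseline == (-2.0, -1.5)

    def test_unknown_kind_raises(self):
        with pytest.raises(KeyError):
            responses.standard_windows("surprise", "LC")


class TestAveragedResponse:
    def test_two_trials_invalid(self):
        est = responses.averaged_response([0.1, 0.2])
        assert not est.valid and est.n_trials == 2

    def test_sham_zero_corrected_equals_mean(self):
        est = responses.averaged_response([0.1, 0.2, 0.3])
        assert est.valid
        assert est.corrected == pytest.approx(est.mean_response)

    def test_sham_subtraction(self):
        est = responses.averaged_response([0.5, 0.5, 0.5], [0.2, 0.2])
        assert est.corrected == pytest.approx(0.3)

    def test_null_activity_centered_on_zero(self):
        # trigger-independent activity: corrected mean within 2 SE of 0
        rng = np.random.default_rng(1)
        x = rng.normal(0, 0.2, 120000)
        spec = WindowSpec((-1.0, 0.0), (0.66, 1.66))
        trig = rng.uniform(5, 1900, 200)
        sham = rng.uniform(5, 1900, 200)
        vals = responses.trial_responses(x, FR, trig, spec)
        shams = responses.trial_responses(x, FR, sham, spec)
        est = responses.averaged_response(vals, shams)
        se = np.nanstd(vals) / np.sqrt(200)
        assert abs(est.corrected) < 2 * 1.5 * se


class TestAbsError:
    def test_closed_loop_coupled_zero(self):
        cfg = synth.SessionConfig(duration=30.0)
        loco = synth.generate_locomotion_trace(cfg, seed=0)
        tl = synth.make_closed_loop(loco, [], cfg)
        assert not np.any(responses.abs_error_trace(tl))

    def test_mismatch_error_equals_speed(self):
        cfg = synth.SessionConfig(duration=30.0)
        tl = synth.make_closed_loop(np.full(cfg.n_samples, 10.0), [12.0], cfg)
        err = responses.abs_error_trace(tl)
        win = slice(int(12 * FR), int(13 * FR))
        np.testing.assert_array_equal(err[win], 10.0)

    def test_stationary_flow_error(self):
        cfg = synth.SessionConfig(duration=30.0)
        tl = synth.make_closed_loop(np.full(cfg.n_samples, 8.0), [], cfg)
        replay = synth.make_open_loop_replay(tl, np.zeros(cfg.n_samples))
        np.testing.assert_array_equal(responses.abs_error_trace(replay), 8.0)

    def test_nonunit_gain_rescales_flow(self):
        tl = synth.make_closed_loop(np.full(1800, 10.0), [],
                                    synth.SessionConfig(duration=30.0, coupling_gain=2.0))
        assert not np.any(responses.abs_error_trace(tl, gain=2.0))

    def test_invalid_gain_raises(self):
        cfg = synth.SessionConfig(duration=10.0)
        tl = synth.make_closed_loop(np.zeros(cfg.n_samples), [], cfg)
        with pytest.raises(ValueError):
            responses.abs_error_trace(tl, gain=0.0)


class TestDeltaAbsError:
    def test_mismatch_step_is_plus_speed(self):
        # closed loop at constant 10 cm/s: error 0 before, 10 during halt
        err = np.zeros(1800)
        err[int(12 * FR): int(13 * FR)] = 10.0
        d = responses.delta_abs_error(err, FR, 12.0, (0.66, 1.66))
        assert d == pytest.approx(10.0, abs=0.1)

    def test_stationary_halt_is_minus_flow(self):
        err = np.full(1800, 8.0)
        err[int(12 * FR): int(13 * FR)] = 0.0
        d = responses.delta_abs_error(err, FR, 12.0, (0.66, 1.66))
        assert d == pytest.approx(-8.0, abs=0.1)

    def test_no_change_zero(self):
        assert responses.delta_abs_error(np.full(1800, 3.0), FR, 12.0,
                                         (0.66, 1.66)) == pytest.approx(0.0)


class TestLmi:
    @pytest.mark.parametrize("a,b,expected", [
        (1.0, 0.0, 1.0),
        (0.0, 1.0, -1.0),
        (3.0, 1.0, 2.0 / np.sqrt(10.0)),
        (1.0, 1.0, 0.0),
    ])
    def test_formula_values(self, a, b, expected):
        assert responses.lmi(a, b).lmi == pytest.approx(expected)

    @given(a=st.floats(-5, 5), b=st.floats(-5, 5), k=st.floats(0.01, 100))
    @settings(max_examples=200, deadline=None)
    def test_antisymmetry_scale_invariance_and_range(self, a, b, k):
        rec = responses.lmi(a, b)
        if not rec.defined:
            return
        assert responses.lmi(b, a).lmi == pytest.approx(-rec.lmi, rel=1e-9, abs=1e-12)
        scaled = responses.lmi(k * a, k * b)
        if scaled.defined:  # scaling can push the denominator under the 0/0 guard
            assert scaled.lmi == pytest.approx(rec.lmi, rel=1e-6, abs=1e-9)
        assert -np.sqrt(2) <= rec.lmi <= np.sqrt(2)

    def test_both_zero_undefined(self):
        assert not responses.lmi(0.0, 0.0).defined


class TestLmiBySpeedBin:
    def test_only_fast_bin_valid(self):
        out = responses.lmi_by_speed_bin([0.2] * 6, [12.0] * 6, r_stat=0.1)
        assert list(out.valid) == [False, False, True]

    def test_boundary_speed_goes_to_lower_bin(self):
        out = responses.lmi_by_speed_bin([0.2] * 4, [5.0] * 4, r_stat=0.1)
        assert out.n_trials.tolist() == [4, 0, 0]

    def test_speed_dependent_suppression_decreases_lmi(self):
        speeds = np.array([2.0] * 5 + [7.0] * 5 + [15.0] * 5)
        vals = 0.3 * (1.0 - 0.04 * speeds)   # responses shrink with speed
        out = responses.lmi_by_speed_bin(vals, speeds, r_stat=0.2)
        lmis = out.lmi.to_numpy()
        assert lmis[0] > lmis[1] > lmis[2]


class TestNormalizeSpeedThreshold:
    def test_identity(self, rng):
        speed = rng.gamma(2, 3, 2000)
        p95 = np.percentile(speed, 95)
        assert responses.normalize_speed_threshold(speed, p95, 4.0) == pytest.approx(4.0)

    def test_halved_speeds_halve_threshold(self, rng):
        speed = rng.gamma(2, 3, 2000)
        p95 = np.percentile(speed, 95)
        got = responses.normalize_speed_threshold(speed / 2, p95, 4.0)
        assert got == pytest.approx(2.0, rel=1e-6)

    def test_zero_p95_raises(self):
        with pytest.raises(ValueError):
            responses.normalize_speed_threshold(np.zeros(100), 10.0, 4.0)


class TestClassifyNeurons:
    def test_equally_spaced_thirds(self):
        closed = np.arange(1.0, 100.0)
        out = responses.classify_neurons(closed, np.zeros_like(closed))
        counts = {c: int(np.sum(out == c)) for c in ("NPE", "other", "PPE")}
        assert all(31 <= v <= 35 for v in counts.values())
        assert out[0] == "NPE" and out[-1] == "PPE"

    def test_all_equal_all_other(self):
        out = responses.classify_neurons(np.full(10, 2.0), np.full(10, 1.0))
        assert np.all(out == "other")

    def test_planted_classes_recovered(self, rng):
        diffs = np.concatenate([rng.normal(-1, 0.05, 40), rng.normal(0, 0.05, 40),
                                rng.normal(1, 0.05, 40)])
        truth = np.array(["NPE"] * 40 + ["other"] * 40 + ["PPE"] * 40)
        out = responses.classify_neurons(diffs, np.zeros_like(diffs))
        assert np.mean(out == truth) >= 0.9

    def test_too_few_neurons_raises(self):
        with pytest.raises(ValueError):
            responses.classify_neurons(np.array([1.0, 2.0]), np.zeros(2))


class TestAxonDensity:
    def test_no_segments_low(self):
        density, cls = responses.axon_density([[]], 1000.0)
        assert density == 0.0 and cls == "low"

    def test_printed_example(self):
        density, cls = responses.axon_density([[400.0, 600.0]], 250_000.0)
        assert density == pytest.approx(0.004)
        assert cls == "high"

    def test_boundary_is_high(self):
        density, cls = responses.axon_density([[500.0]], 250_000.0)
        assert density == pytest.approx(0.002)
        assert cls == "high"

    def test_average_over_images(self):
        density, _ = responses.axon_density([[1000.0], [0.0]], 250_000.0)
        assert density == pytest.approx(0.002)

    def test_bad_area_raises(self):
        with pytest.raises(ValueError):
            responses.axon_density([[10.0]], 0.0)


class TestPupilResponse:
    def test_constant_trace_raises(self):
        with pytest.raises(ValueError):
            responses.pupil_response(np.full(3000, 5.0), 30.0, [10.0])

    def test_dilation_recovered_in_z_units(self, rng):
        fr = 30.0
        diam = 50.0 + rng.normal(0, 0.5, 9000)
        for t in (60.0, 120.0, 180.0):
            i = int(t * fr)
            diam[i: i + int(2 * fr)] += 5.0
        est = responses.pupil_response(diam, fr, [60.0, 120.0, 180.0],
                                       response_window=(0.0, 2.0))
        assert est.valid and est.mean_response > 1.0

    def test_blink_trials_excluded(self, rng):
        fr = 30.0
        diam = 50.0 + rng.normal(0, 0.5, 9000)
        blink = np.zeros(9000, bool)
        blink[int(60.5 * fr): int(60.7 * fr)] = True
        est = responses.pupil_response(diam, fr, [60.0, 120.0, 180.0, 240.0],
                                       blink_mask=blink)
        assert est.n_trials == 3


class TestDetectBlinks:
    def test_flags_dropouts_and_spikes(self, rng):
        fr = 30.0
        diam = 50.0 + rng.normal(0, 0.2, 3000)
        diam[900:915] = 10.0  # blink dropout
        mask = responses.detect_blinks(diam, fr)
        assert mask[900:915].all()
        assert mask.mean() < 0.05

    def test_clean_trace_mostly_unflagged(self, rng):
        diam = 50.0 + np.cumsum(rng.normal(0, 0.01, 3000))
        assert responses.detect_blinks(diam, 30.0).mean() < 0.02
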