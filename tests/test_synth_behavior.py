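"""Behavior/stimulus generators: bout process, schedulers, coupling, opto."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mismatch2p import responses, synth
from mismatch2p.session import CONDITION_CODES


class TestLocomotionTrace:
    def test_no_locomotion_limit(self):
        cfg = synth.SessionConfig(duration=60.0, bout_probability=0.0)
        assert not np.any(synth.generate_locomotion_trace(cfg, seed=0))

    def test_deterministic_under_seed(self):
        cfg = synth.SessionConfig(duration=120.0)
        a = synth.generate_locomotion_trace(cfg, seed=7)
        b = synth.generate_locomotion_trace(cfg, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_nonnegative_and_bout_structure(self):
        cfg = synth.SessionConfig(duration=300.0)
        tr = synth.generate_locomotion_trace(cfg, seed=3)
        assert np.all(tr >= 0)
        # both stationary (<0.4) and vigorous (>2) epochs must occur
        assert np.mean(tr < 0.4) > 0.1
        assert np.mean(tr > 2.0) > 0.1

    def test_locomoting_fraction_matches_dwell_design(self):
        # equal bout/stationary dwell means target a ~50% duty cycle;
        # fraction of samples above the 4 cm/s inclusion speed, averaged
        # over 20 seeds, should sit within 5 points of it
        cfg = synth.SessionConfig(duration=600.0)
        frac = np.mean([
            np.mean(synth.generate_locomotion_trace(cfg, seed=s) > 4.0)
            for s in range(20)
        ])
        assert abs(frac - 0.5) < 0.05

    def test_empty_trace_error(self):
        with pytest.raises(ValueError):
            synth.SessionConfig(duration=-1.0)


class TestScheduleEvents:
    def test_zero_duration_empty(self):
        assert synth.schedule_events(0.0, 12, 2, seed=0).size == 0

    def test_degenerate_sd_periodic(self):
        t = synth.schedule_events(100.0, 10.0, 0.0, seed=0)
        np.testing.assert_allclose(np.diff(t), 10.0)

    def test_gap_moments_near_nominal(self):
        t = synth.schedule_events(15000.0, 12.0, 2.0, seed=1)
        gaps = np.diff(t)
        assert len(gaps) > 1000
        se = 2.0 / np.sqrt(len(gaps))
        assert abs(gaps.mean() - 12.0) < 3 * se
        assert abs(gaps.std(ddof=1) - 2.0) < 0.15

    @given(mean=st.floats(3.0, 20.0), sd=st.floats(0.0, 4.0),
           seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_sorted_in_range_above_floor(self, mean, sd, seed):
        t = synth.schedule_events(500.0, mean, sd, seed=seed, floor=2.0)
        assert np.all(np.diff(t) >= 2.0 - 1e-9)
        assert np.all((t >= 0) & (t < 500.0))

    def test_invalid_mean_raises(self):
        with pytest.raises(ValueError):
            synth.schedule_events(100.0, -1.0, 2.0)


class TestClosedLoop:
    def test_zero_locomotion_zero_flow(self):
        cfg = synth.SessionConfig(duration=30.0)
        tl = synth.make_closed_loop(np.zeros(cfg.n_samples), [10.0], cfg)
        assert not np.any(tl.visual_flow)

    def test_mismatch_clamps_flow_to_zero(self):
        cfg = synth.SessionConfig(duration=30.0)
        loco = np.full(cfg.n_samples, 10.0)
        tl = synth.make_closed_loop(loco, [12.0], cfg)
        fr = cfg.frame_rate
        win = slice(int(12.0 * fr), int(13.0 * fr))
        assert not np.any(tl.visual_flow[win])
        outside = np.ones(cfg.n_samples, bool)
        outside[win] = False
        np.testing.assert_array_equal(tl.visual_flow[outside], 10.0)

    def test_coupling_identity_and_error_trace(self):
        cfg = synth.SessionConfig(duration=60.0)
        loco = synth.generate_locomotion_trace(cfg, seed=2)
        tl = synth.make_closed_loop(loco, [20.0, 40.0], cfg)
        err = responses.abs_error_trace(tl)
        mask = np.ones(cfg.n_samples, bool)
        fr = cfg.frame_rate
        for t in (20.0, 40.0):
            mask[int(t * fr): int((t + 1.0) * fr)] = False
        assert np.all(err[mask] == 0.0)  # exact coupling outside halts

    def test_overlapping_windows_warn(self):
        cfg = synth.SessionConfig(duration=30.0)
        with pytest.warns(UserWarning, match="merged"):
            synth.make_closed_loop(np.ones(cfg.n_samples), [5.0, 5.5], cfg)

    def test_trigger_outside_trace_raises(self):
        cfg = synth.SessionConfig(duration=30.0)
        with pytest.raises(ValueError):
            synth.make_closed_loop(np.ones(cfg.n_samples), [40.0], cfg)


class TestOpenLoopReplay:
    @pytest.fixture()
    def closed(self):
        cfg = synth.SessionConfig(duration=60.0)
        loco = synth.generate_locomotion_trace(cfg, seed=4)
        return cfg, loco, synth.make_closed_loop(loco, [15.0, 30.0], cfg)

    def test_flow_copied_and_halts_renamed(self, closed):
        _, _, tl = closed
        replay = synth.make_open_loop_replay(tl, np.zeros(tl.n_samples))
        np.testing.assert_array_equal(replay.visual_flow, tl.visual_flow)
        np.testing.assert_array_equal(replay.trigger_times("playback_halt"),
                                      tl.trigger_times("mismatch"))
        assert np.all(replay.condition == CONDITION_CODES["open_loop_replay"])

    def test_identical_locomotion_degenerate_replay(self, closed):
        _, loco, tl = closed
        replay = synth.make_open_loop_replay(tl, loco)
        err = responses.abs_error_trace(replay)
        mask = np.ones(tl.n_samples, bool)
        for t in (15.0, 30.0):
            mask[int(t * 60): int((t + 1) * 60)] = False
        assert np.all(err[mask] == 0.0)

    def test_stationary_replay_error_equals_flow(self, closed):
        _, _, tl = closed
        replay = synth.make_open_loop_replay(tl, np.zeros(tl.n_samples))
        np.testing.assert_array_equal(responses.abs_error_trace(replay), replay.visual_flow)

    def test_length_mismatch_raises(self, closed):
        _, _, tl = closed
        with pytest.raises(ValueError):
            synth.make_open_loop_replay(tl, np.zeros(10))


class TestOptoTrain:
    def test_duty_cycle_exact(self):
        cfg = synth.SessionConfig(duration=60.0)
        assert synth.opto_duty_cycle(cfg) == pytest.approx(0.30)
        laser, times = synth.make_opto_train(cfg, seed=0, sample_rate=1000.0)
        assert len(times) > 0
        for t in times:
            i0 = int(round(t * 1000))
            train = laser[i0: i0 + 1000]
            assert train.mean() == pytest.approx(0.30)

    def test_twenty_pulses_per_train(self):
        cfg = synth.SessionConfig(duration=30.0)
        laser, times = synth.make_opto_train(cfg, seed=1, sample_rate=1000.0)
        i0 = int(round(times[0] * 1000))
        train = laser[i0: i0 + 1000]
        n_pulses = np.sum(np.diff(np.concatenate([[0], train])) == 1)
        assert n_pulses == 20

    def test_zero_train_duration_all_off(self):
        cfg = synth.SessionConfig(duration=30.0)
        cfg.opto_train_duration = 0.0
        laser, times = synth.make_opto_train(cfg, seed=0)
        assert not laser.any() and times.size == 0

    def test_invalid_duty_cycle_raises(self):
        cfg = synth.SessionConfig(duration=30.0)
        cfg.opto_pulse_width = 0.06  # 0.06 * 20 Hz > 1
        with pytest.raises(ValueError, match="duty"):
            synth.make_opto_train(cfg, seed=0)

    def test_locomotion_gating(self):
        cfg = synth.SessionConfig(duration=120.0, opto_loco_gated=True)
        loco = np.zeros(cfg.n_samples)
        loco[: cfg.n_samples // 2] = 10.0  # running only in the first half
        laser, times = synth.make_opto_train(cfg, duration=120.0, loco=loco, seed=2)
        assert len(times) > 0
        assert np.all(times < 60.5)
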