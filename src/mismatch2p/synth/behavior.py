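"""Behavior and stimulus generators: locomotion bouts, event schedules,
closed-loop coupling, open-loop replay, optogenetic pulse trains.

Locomotion is a two-state semi-Markov bout process: the animal alternates
between stationary epochs (sub-0.4 cm/s jitter) and locomotion bouts with
a plateau speed drawn per bout, with exponential dwell times in each
state and smoothed transitions.  Stimulus schedules draw successive gaps
from a normal distribution truncated at a floor (events every
mean ± SD seconds, regardless of behavior).  Closed-loop coupling yokes
visual-flow speed to locomotion (flow = gain × locomotion) except during
1 s mismatch halts where flow is clamped to zero; open-loop replay plays
the same flow trace against fresh locomotion, turning former mismatches
into playback halts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import truncnorm

from ..config import DEFAULTS
from ..session import CONDITION_CODES, SessionTimeline


@dataclass
class SessionConfig:
    """Parameters of one simulated virtual-reality session.

    Frame rate is 60 Hz for single-plane axonal sessions and 15 Hz for
    four-plane somatic sessions.  Flow speeds are locomotion-equivalent
    cm/s, so coupling_gain defaults to 1.  The two fixed-speed flow
    protocols differ only in their gap statistics: 9 ± 3 s for the
    stimulation-response protocol, 7 ± 1 s for the plasticity protocol.
    """

    frame_rate: float = DEFAULTS["frame_rate_lc_hz"]
    duration: float = 360.0
    coupling_gain: float = DEFAULTS["coupling_gain"]
    mismatch_interval_mean: float = DEFAULTS["mismatch_interval_mean_s"]
    mismatch_interval_sd: float = DEFAULTS["mismatch_interval_sd_s"]
    mismatch_duration: float = DEFAULTS["mismatch_duration_s"]
    flow_stim_interval_mean: float = DEFAULTS["flow_stim_interval_plast_mean_s"]
    flow_stim_interval_sd: float = DEFAULTS["flow_stim_interval_plast_sd_s"]
    flow_stim_duration: float = DEFAULTS["flow_stim_duration_s"]
    flow_stim_speed: float = DEFAULTS["flow_stim_speed_cmps"]
    flow_stim_directions: tuple = ("NT", "TN")
    opto_pulse_width: float = DEFAULTS["opto_pulse_width_s"]
    opto_pulse_rate: float = DEFAULTS["opto_pulse_rate_hz"]
    opto_train_duration: float = DEFAULTS["opto_train_duration_s"]
    opto_train_interval_mean: float = DEFAULTS["opto_train_interval_mean_s"]
    opto_train_interval_sd: float = DEFAULTS["opto_train_interval_sd_s"]
    opto_loco_gated: bool = False
    opto_loco_gate_threshold: float = DEFAULTS["opto_loco_gate_cmps"]
    interval_floor: float = DEFAULTS["interval_floor_s"]
    # bout-process parameters (behavior statistics are a generator choice)
    bout_dwell_mean: float = 8.0        # s in a locomotion bout
    stationary_dwell_mean: float = 8.0  # s stationary
    bout_speed_range: tuple = (5.0, 25.0)   # plateau cm/s, uniform per bout
    bout_probability: float = 1.0       # 0 disables locomotion entirely
    transition_smoothing: float = 0.25  # s, Gaussian sigma on the speed trace
    stationary_jitter: float = 0.05     # cm/s, sub-threshold noise when still
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        for name in ("mismatch_interval_mean", "mismatch_duration", "flow_stim_interval_mean",
                     "flow_stim_duration", "opto_train_duration", "opto_train_interval_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mismatch_interval_mean <= self.mismatch_duration:
            raise ValueError("mismatch interval mean must exceed mismatch duration")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.frame_rate))

    def to_json(self) -> str:
        d = asdict(self)
        d["flow_stim_directions"] = list(d["flow_stim_directions"])
        d["bout_speed_range"] = list(d["bout_speed_range"])
        return json.dumps(d, sort_keys=True)


def generate_locomotion_trace(config: SessionConfig, seed=None) -> np.ndarray:
    """Nonnegative locomotion-speed trace (cm/s) from the bout process.

    Alternating stationary/bout epochs with exponential dwell times
    (means from the config), plateau speed uniform per bout, Gaussian
    transition smoothing, and sub-threshold jitter when stationary.
    Deterministic for a fixed seed; bout_probability 0 yields an
    all-zero-mean jitter-free trace.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_samples
    if n <= 0:
        raise ValueError("non-positive duration yields an empty trace")
    fr = config.frame_rate
    speed = np.zeros(n)
    if config.bout_probability <= 0:
        return speed
    t = 0
    in_bout = rng.random() < 0.5
    while t < n:
        if in_bout and rng.random() < config.bout_probability:
            dwell = max(1, int(round(rng.exponential(config.bout_dwell_mean) * fr)))
            speed[t : t + dwell] = rng.uniform(*config.bout_speed_range)
        else:
            dwell = max(1, int(round(rng.exponential(config.stationary_dwell_mean) * fr)))
        t += dwell
        in_bout = not in_bout
    if config.transition_smoothing > 0:
        speed = gaussian_filter1d(speed, config.transition_smoothing * fr)
    still = speed < 0.1
    if config.stationary_jitter > 0:
        speed[still] += rng.uniform(0, config.stationary_jitter, size=int(still.sum()))
    return np.clip(speed, 0, None)


def schedule_events(
    duration: float,
    interval_mean: float,
    interval_sd: float,
    seed=0,
    floor: float = DEFAULTS["interval_floor_s"],
) -> np.ndarray:
    """Sorted trigger times with gaps ~ Normal(mean, sd) truncated at ``floor``.

    Events are scheduled regardless of behavior; the first event is one
    gap after t=0 and all triggers lie in [0, duration).  sd=0 gives an
    exactly periodic schedule.  Non-positive duration returns an empty
    list.
    """
    if interval_mean <= 0:
        raise ValueError("interval_mean must be positive")
    if interval_sd < 0:
        raise ValueError("interval_sd must be nonnegative")
    if duration <= 0:
        return np.empty(0)
    rng = np.random.default_rng(seed)
    n_gaps = int(np.ceil(duration / max(interval_mean - 3 * interval_sd, 1e-3))) + 10
    if interval_sd == 0:
        gaps = np.full(n_gaps, interval_mean)
    else:
        a = (floor - interval_mean) / interval_sd
        gaps = truncnorm.rvs(a, np.inf, loc=interval_mean, scale=interval_sd,
                             size=n_gaps, random_state=rng)
    times = np.cumsum(gaps)
    while times[-1] < duration:  # pathological short draw; extend
        times = np.concatenate([times, times[-1] + np.cumsum(
            truncnorm.rvs((floor - interval_mean) / max(interval_sd, 1e-9), np.inf,
                          loc=interval_mean, scale=max(interval_sd, 1e-9),
                          size=n_gaps, random_state=rng))])
    return times[times < duration]


def make_closed_loop(
    loco: np.ndarray, mismatch_triggers: np.ndarray, config: SessionConfig
) -> SessionTimeline:
    """Closed-loop timeline: flow yoked to locomotion, clamped to zero
    for ``mismatch_duration`` after each mismatch trigger.

    Overlapping mismatch windows are merged with a warning; the clamp —
    not the trigger list — defines the halt extent, so |Error| is zero
    everywhere outside the clamped windows.
    """
    loco = np.asarray(loco, dtype=float)
    n = len(loco)
    fr = config.frame_rate
    triggers = np.sort(np.asarray(mismatch_triggers, dtype=float))
    if triggers.size and (triggers[0] < 0 or triggers[-1] >= n / fr):
        raise ValueError("mismatch triggers outside trace extent")
    if triggers.size > 1 and np.any(np.diff(triggers) < config.mismatch_duration):
        warnings.warn("overlapping mismatch windows merged")
    flow = config.coupling_gain * loco
    for t in triggers:
        i0 = int(round(t * fr))
        i1 = min(n, i0 + int(round(config.mismatch_duration * fr)))
        flow[i0:i1] = 0.0
    return SessionTimeline(
        time=np.arange(n) / fr,
        locomotion=loco,
        visual_flow=flow,
        condition=np.full(n, CONDITION_CODES["closed_loop"], dtype=np.int8),
        triggers={"mismatch": triggers},
        frame_rate=fr,
    )


def make_open_loop_replay(closed: SessionTimeline, new_loco: np.ndarray) -> SessionTimeline:
    """Replay the closed-loop flow against fresh locomotion.

    The flow trace is copied verbatim; former mismatch times become
    playback_halt triggers; the condition label flips to
    open_loop_replay.
    """
    if not np.all(closed.condition == CONDITION_CODES["closed_loop"]):
        raise ValueError("replay source must be a closed-loop timeline")
    new_loco = np.asarray(new_loco, dtype=float)
    if len(new_loco) != closed.n_samples:
        raise ValueError("replacement locomotion length mismatch")
    return SessionTimeline(
        time=closed.time.copy(),
        locomotion=new_loco,
        visual_flow=closed.visual_flow.copy(),
        condition=np.full(closed.n_samples, CONDITION_CODES["open_loop_replay"], dtype=np.int8),
        triggers={"playback_halt": closed.trigger_times("mismatch").copy()},
        frame_rate=closed.frame_rate,
    )


def make_fixed_flow_timeline(
    loco: np.ndarray,
    config: SessionConfig,
    seed=0,
    directions: tuple = None,
) -> SessionTimeline:
    """Open-loop fixed-speed flow stimuli (1 s, 24 cm/s-equivalent),
    scheduled at the config's flow-stim gap statistics with directions
    drawn pseudorandomly per stimulus."""
    loco = np.asarray(loco, dtype=float)
    n = len(loco)
    fr = config.frame_rate
    rng = np.random.default_rng(seed)
    times = schedule_events(n / fr - config.flow_stim_duration - 1.0,
                            config.flow_stim_interval_mean,
                            config.flow_stim_interval_sd, seed=rng,
                            floor=config.interval_floor)
    directions = config.flow_stim_directions if directions is None else directions
    dirs = [directions[i] for i in rng.integers(0, len(directions), size=len(times))]
    flow = np.zeros(n)
    trig = {f"flow_onset_{d}": [] for d in directions}
    for t, d in zip(times, dirs):
        i0 = int(round(t * fr))
        i1 = min(n, i0 + int(round(config.flow_stim_duration * fr)))
        flow[i0:i1] = config.flow_stim_speed
        trig[f"flow_onset_{d}"].append(t)
    return SessionTimeline(
        time=np.arange(n) / fr,
        locomotion=loco,
        visual_flow=flow,
        condition=np.full(n, CONDITION_CODES["open_loop_fixed"], dtype=np.int8),
        triggers={k: np.asarray(v) for k, v in trig.items()},
        frame_rate=fr,
    )


def make_opto_train(
    config: SessionConfig,
    duration: float = None,
    loco: np.ndarray = None,
    seed=0,
    sample_rate: float = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary laser trace and train-onset times.

    Each 1 s train carries 15 ms pulses at 20 Hz (pulse_rate × duration
    pulses; duty cycle pulse_width × pulse_rate = 30% at defaults).
    Trains are scheduled at the config's train gap statistics; with
    ``opto_loco_gated`` a train is emitted only if locomotion exceeds
    the gate threshold at its scheduled time.  The trace is sampled at
    ``sample_rate`` (default: the session frame rate).
    """
    duty = config.opto_pulse_width * config.opto_pulse_rate
    if duty > 1:
        raise ValueError("pulse_width x pulse_rate exceeds 1: invalid duty cycle")
    fr = config.frame_rate if sample_rate is None else sample_rate
    duration = config.duration if duration is None else duration
    n = int(round(duration * fr))
    laser = np.zeros(n, dtype=np.uint8)
    if config.opto_train_duration <= 0:
        return laser, np.empty(0)
    times = schedule_events(max(duration - config.opto_train_duration, 0.0),
                            config.opto_train_interval_mean,
                            config.opto_train_interval_sd, seed=seed,
                            floor=config.interval_floor)
    if config.opto_loco_gated and loco is not None:
        loco = np.asarray(loco, dtype=float)
        loco_fr = len(loco) / duration
        gate = np.array([loco[min(int(round(t * loco_fr)), len(loco) - 1)]
                         > config.opto_loco_gate_threshold for t in times])
        times = times[gate]
    n_pulses = int(round(config.opto_pulse_rate * config.opto_train_duration))
    period = 1.0 / config.opto_pulse_rate
    for t in times:
        for k in range(n_pulses):
            i0 = int(round((t + k * period) * fr))
            i1 = int(round((t + k * period + config.opto_pulse_width) * fr))
            laser[i0:min(i1, n)] = 1
    return laser, times


def opto_duty_cycle(config: SessionConfig) -> float:
    """Analytic within-train duty cycle: pulse_width × pulse_rate."""
    return config.opto_pulse_width * config.opto_pulse_rate
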