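"""Event detection, trial-state classification, and sham triggers.

Locomotion (and, in open-loop replay, visual-flow) onsets are threshold
crossings of 0.4 cm/s with a quiet 2 s pre-window (mean < 0.4 cm/s) and a
vigorous 1 s post-window (mean > 2 cm/s).  Trials are classified by mean
locomotion speed around the trigger under one of two schemes: the axon
(LC) scheme thresholds the 1 s after the trigger at 1 cm/s (fast > 10,
slow in (1, 10]); the somatic (V1) scheme thresholds the 1 s stimulus
window at 4 cm/s for locomotion and 1 cm/s for stationary, leaving a
gap of unclassified trials.  Sham triggers are uniform random times
sub-selected by the same classifier, used downstream to subtract
behavior-conditioned baseline bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .config import DEFAULTS

LOCOMOTION_STATES = ("locomotion", "stationary", "fast", "slow", "unclassified")


@dataclass
class TriggerSet:
    """Trigger times of one kind with per-trigger classifications."""

    kind: str
    times: np.ndarray
    locomotion_state: list = field(default_factory=list)
    flow_context: list = field(default_factory=list)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise ValueError("trigger times must be sorted")

    def to_frame(self) -> pd.DataFrame:
        n = len(self.times)
        return pd.DataFrame(
            {
                "kind": [self.kind] * n,
                "time_s": self.times,
                "state": list(self.locomotion_state) or [""] * n,
                "flow_context": list(self.flow_context) or [""] * n,
            }
        )


def _window_mean(trace: np.ndarray, frame_rate: float, t0: float, t1: float) -> float:
    i0 = int(round(t0 * frame_rate))
    i1 = int(round(t1 * frame_rate))
    if i0 < 0 or i1 > len(trace) or i1 <= i0:
        raise ValueError(f"window [{t0}, {t1}] s out of trace range")
    return float(np.mean(trace[i0:i1]))


def detect_onsets(
    speed: np.ndarray,
    frame_rate: float,
    cross: float = DEFAULTS["onset_cross_cmps"],
    pre_window: float = DEFAULTS["onset_pre_window_s"],
    post_window: float = DEFAULTS["onset_post_window_s"],
    post_mean: float = DEFAULTS["onset_post_mean_cmps"],
    refractory: float = None,
) -> np.ndarray:
    """Times (s) where speed crosses ``cross`` upward after a quiet
    pre-window and before a vigorous post-window.

    Criteria: speed crosses 0.4 cm/s; mean of the previous 2 s < 0.4 cm/s;
    mean of the following 1 s > 2 cm/s.  The same rule applies verbatim to
    visual-flow traces for flow onsets in replay.  A refractory spacing
    (default = pre_window) suppresses duplicate onsets within one
    acceleration.
    """
    speed = np.asarray(speed, dtype=float)
    if refractory is None:
        refractory = pre_window
    n_pre = int(round(pre_window * frame_rate))
    n_post = int(round(post_window * frame_rate))
    if len(speed) <= n_pre + n_post:
        return np.empty(0)
    crossings = np.flatnonzero((speed[:-1] < cross) & (speed[1:] >= cross)) + 1
    onsets = []
    last = -np.inf
    for i in crossings:
        if i < n_pre or i + n_post > len(speed):
            continue
        t = i / frame_rate
        if t - last < refractory:
            continue
        if np.mean(speed[i - n_pre : i]) >= cross:
            continue
        if np.mean(speed[i : i + n_post]) <= post_mean:
            continue
        onsets.append(t)
        last = t
    return np.asarray(onsets)


def classify_trial_state(
    speed: np.ndarray,
    frame_rate: float,
    trigger: float,
    scheme: str,
    stimulus_window: float = 1.0,
    loco_threshold: float = None,
    stat_threshold: float = None,
) -> str:
    """Locomotion state of one trial.

    LC scheme: mean speed in [trigger, trigger+1 s] > 1 cm/s → locomotion
    (fast if > 10 cm/s, slow otherwise), else stationary.  V1 scheme:
    mean speed over the 1 s stimulus window > 4 cm/s → locomotion,
    < 1 cm/s → stationary, otherwise unclassified.  Thresholds may be
    overridden (e.g., after 95th-percentile normalization across
    datasets).
    """
    m = _window_mean(speed, frame_rate, trigger, trigger + stimulus_window)
    if scheme == "LC":
        loco = DEFAULTS["lc_loco_threshold_cmps"] if loco_threshold is None else loco_threshold
        fast = DEFAULTS["lc_fast_threshold_cmps"]
        if m > loco:
            return "fast" if m > fast else "slow"
        return "stationary"
    if scheme == "V1":
        loco = DEFAULTS["v1_loco_threshold_cmps"] if loco_threshold is None else loco_threshold
        stat = DEFAULTS["v1_stat_threshold_cmps"] if stat_threshold is None else stat_threshold
        if m > loco:
            return "locomotion"
        if m < stat:
            return "stationary"
        return "unclassified"
    raise ValueError(f"unknown scheme {scheme!r}")


def state_matches(state: str, criterion: str) -> bool:
    """Whether a classified state satisfies a selection criterion.

    ``locomotion`` matches fast/slow/locomotion; other criteria match
    exactly.
    """
    if criterion == "locomotion":
        return state in ("locomotion", "fast", "slow")
    return state == criterion


def classify_onset_flow_context(
    flow: np.ndarray,
    frame_rate: float,
    onset: float,
    window: float = DEFAULTS["flow_context_window_s"],
    threshold: float = DEFAULTS["flow_context_threshold_cmps"],
    gain: float = 1.0,
) -> str:
    """Visual-flow context of a locomotion onset.

    ``no_visual_flow`` iff mean flow speed in the 2 s window centered on
    the onset is below the flow equivalent of 1 cm/s locomotion
    (threshold × gain); at or above → ``visual_flow`` (strict "below"
    rule).
    """
    m = _window_mean(flow, frame_rate, onset - window / 2, onset + window / 2)
    return "no_visual_flow" if m < threshold * gain else "visual_flow"


def draw_sham_triggers(
    n: int,
    valid_range: tuple,
    state_criterion: str,
    speed: np.ndarray,
    frame_rate: float,
    scheme: str,
    rng,
    stimulus_window: float = 1.0,
    real_triggers: np.ndarray = None,
    exclusion_margin: float = None,
    loco_threshold: float = None,
    stat_threshold: float = None,
) -> np.ndarray:
    """Random candidate times sub-selected by the trial-state classifier.

    ``n`` uniform candidates are drawn in ``valid_range`` (shrunk by the
    window margins), times within ``exclusion_margin`` of any real trigger
    are discarded, and the survivors are filtered with the same
    classify_trial_state criterion as the matched real stimulus.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    lo = max(valid_range[0], 2.0)  # room for a 1-2 s baseline window
    hi = min(valid_range[1], len(speed) / frame_rate) - max(stimulus_window, 4.0)
    if hi <= lo:
        warnings.warn("no room for sham triggers in range")
        return np.empty(0)
    candidates = np.sort(rng.uniform(lo, hi, size=n))
    if real_triggers is not None and len(real_triggers):
        margin = stimulus_window if exclusion_margin is None else exclusion_margin
        real = np.asarray(real_triggers, dtype=float)
        dist = np.min(np.abs(candidates[:, None] - real[None, :]), axis=1)
        candidates = candidates[dist >= margin]
    kept = [
        t
        for t in candidates
        if state_matches(
            classify_trial_state(
                speed, frame_rate, t, scheme, stimulus_window, loco_threshold, stat_threshold
            ),
            state_criterion,
        )
    ]
    if not kept:
        warnings.warn(f"no sham candidates satisfied criterion {state_criterion!r}")
    return np.asarray(kept)


def session_passes_inclusion(
    speed: np.ndarray,
    threshold: float = DEFAULTS["inclusion_speed_cmps"],
    min_fraction: float = DEFAULTS["inclusion_min_fraction"],
) -> bool:
    """Session inclusion rule: ≥15% of samples locomoting above 4 cm/s.

    Sessions below this spend too little time in visuomotor coupling to
    assay locomotion-dependent responses.
    """
    speed = np.asarray(speed, dtype=float)
    if speed.size == 0:
        raise ValueError("empty speed trace")
    return float(np.mean(speed > threshold)) >= min_fraction
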