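"""Synthetic LC-axon sessions driven by unsigned visuomotor error.

The latent axonal activity rate is

    r(t) = baseline + error_gain · |Error|(t) + loco_onset_gain · K(t)

where |Error|(t) = |locomotion − flow| on the session timeline and K is
an onset kernel placed at detected locomotion onsets.  Under closed-loop
coupling |Error| is zero outside mismatch halts, so mismatches during
locomotion drive positive transients that scale with running speed;
during open-loop replay a stationary animal sees |Error| = flow, so a
playback halt *removes* error drive and deflects the rate (and ΔF/F)
negative.  Several axon-segment ROIs per field of view share the latent
rate (with per-ROI gain jitter) plus independent noise, reproducing the
high within-FoV correlation of axonal imaging.  Mouse- and FoV-level
lognormal random effects on the gains create the nested variance
structure hierarchical statistics need.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .. import events
from ..session import RoiSet, Session, SessionTimeline, concat_timelines
from .behavior import (SessionConfig, generate_locomotion_trace,
                       make_closed_loop, make_open_loop_replay, schedule_events)
from .calcium import CalciumParams, calcium_kernel, simulate_fluorescence


@dataclass
class LcAxonModel:
    """Gains of the unsigned-error model of LC axonal activity."""

    error_gain: float = 0.08          # rate units per cm/s of |Error|
    loco_onset_gain: float = 0.5      # rate units at a locomotion onset
    baseline_rate: float = 0.0
    rectify_negative: bool = False    # clamp rate at zero if True
    roi_gain_jitter_sd: float = 0.1   # lognormal sd across ROIs in a FoV
    fov_effect_sd: float = 0.15       # lognormal sd of per-FoV gain
    mouse_effect_sd: float = 0.15     # lognormal sd of per-mouse gain
    n_rois: int = 6

    def __post_init__(self):
        if self.error_gain < 0:
            raise ValueError("error_gain must be nonnegative")


def _onset_drive(loco: np.ndarray, frame_rate: float) -> np.ndarray:
    """Unit-area 1 s triangular kernel at each detected locomotion onset."""
    onsets = events.detect_onsets(loco, frame_rate)
    drive = np.zeros(len(loco))
    width = int(round(1.0 * frame_rate))
    kernel = np.concatenate([np.linspace(0, 1, width // 2), np.linspace(1, 0, width - width // 2)])
    kernel /= kernel.sum() / frame_rate  # unit time-integral
    for t in onsets:
        i = int(round(t * frame_rate))
        seg = kernel[: len(drive) - i]
        drive[i : i + len(seg)] += seg
    return drive


def simulate_lc_session(
    config: SessionConfig,
    model: LcAxonModel,
    seed=0,
    mouse_gain: float = None,
    mouse_id: str = "m00",
    site_id: str = "s00",
    calcium: CalciumParams = None,
) -> Session:
    """One axonal session: closed loop with mismatches, then open-loop
    replay of the same flow against fresh locomotion.

    Returns a Session whose RoiSet holds ``model.n_rois`` axon-segment
    traces sharing one latent rate.  ``mouse_gain`` lets a dataset-level
    caller impose a common per-mouse random effect.
    """
    rng = np.random.default_rng(seed)
    fr = config.frame_rate
    calcium = calcium or CalciumParams.gcamp6s_like(noise_sd=1.5, amplitude=40.0)

    loco_cl = generate_locomotion_trace(config, seed=rng.integers(2**31))
    mm = schedule_events(config.duration - config.mismatch_duration,
                         config.mismatch_interval_mean, config.mismatch_interval_sd,
                         seed=rng.integers(2**31), floor=config.interval_floor)
    closed = make_closed_loop(loco_cl, mm, config)
    loco_ol = generate_locomotion_trace(config, seed=rng.integers(2**31))
    replay = make_open_loop_replay(closed, loco_ol)
    timeline = concat_timelines(closed, replay)

    abs_err = np.abs(timeline.locomotion - timeline.visual_flow / config.coupling_gain)
    if mouse_gain is None:
        mouse_gain = float(rng.lognormal(0.0, model.mouse_effect_sd))
    fov_gain = mouse_gain * float(rng.lognormal(0.0, model.fov_effect_sd))
    rate = (model.baseline_rate
            + fov_gain * model.error_gain * abs_err
            + fov_gain * model.loco_onset_gain * _onset_drive(timeline.locomotion, fr))
    if model.rectify_negative:
        rate = np.clip(rate, 0, None)

    traces = []
    for _ in range(model.n_rois):
        roi_gain = float(rng.lognormal(0.0, model.roi_gain_jitter_sd))
        traces.append(simulate_fluorescence(roi_gain * rate, calcium, fr,
                                            seed=rng.integers(2**31)))
    rois = RoiSet(np.stack(traces), frame_rate=fr)
    return Session(timeline=timeline, rois=rois, mouse_id=mouse_id, site_id=site_id,
                   scheme="LC", seed=int(seed), config_json=config.to_json())


def simulate_lc_dataset(
    config: SessionConfig,
    model: LcAxonModel,
    n_mice: int = 3,
    n_fovs_per_mouse: int = 2,
    seed=0,
) -> list[Session]:
    """Independent sessions over a nested mouse → FoV design."""
    rng = np.random.default_rng(seed)
    sessions = []
    for m in range(n_mice):
        mouse_gain = float(rng.lognormal(0.0, model.mouse_effect_sd))
        for f in range(n_fovs_per_mouse):
            sessions.append(
                simulate_lc_session(
                    config, model, seed=rng.integers(2**31), mouse_gain=mouse_gain,
                    mouse_id=f"m{m:02d}", site_id=f"m{m:02d}_fov{f:02d}",
                )
            )
    return sessions
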