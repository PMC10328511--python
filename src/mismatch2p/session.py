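"""Core in-memory containers for a virtual-reality imaging session.

A session pairs synchronized behavior/stimulus time series (locomotion
speed, visual-flow speed, condition labels, trigger lists) with per-ROI
fluorescence, and optionally pupil and optogenetic-laser records.  Visual
flow speed is stored in locomotion-equivalent cm/s, so under closed-loop
coupling with unit gain the flow trace equals the locomotion trace sample
for sample.  Flow direction (nasotemporal vs temporonasal) is metadata on
triggers, never a sign on the speed trace.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

#: Condition labels and their integer codes in the HDF5 layout.
CONDITION_CODES = {"closed_loop": 0, "open_loop_replay": 1, "open_loop_fixed": 2}
CONDITION_LABELS = {v: k for k, v in CONDITION_CODES.items()}

#: Trigger kinds a timeline may carry.
TRIGGER_KINDS = (
    "mismatch",
    "playback_halt",
    "flow_onset_NT",
    "flow_onset_TN",
    "opto_train",
    "air_puff",
)


@dataclass
class SessionTimeline:
    """Synchronized behavior/stimulus time series with trigger lists.

    Attributes
    ----------
    time : (n,) array, seconds from session start
    locomotion : (n,) array, cm/s, nonnegative
    visual_flow : (n,) array, locomotion-equivalent cm/s, nonnegative
    condition : (n,) int array of CONDITION_CODES values
    triggers : dict kind -> sorted float array of event times (s)
    frame_rate : Hz
    """

    time: np.ndarray
    locomotion: np.ndarray
    visual_flow: np.ndarray
    condition: np.ndarray
    triggers: dict = field(default_factory=dict)
    frame_rate: float = 60.0

    def __post_init__(self):
        n = len(self.time)
        if not (len(self.locomotion) == len(self.visual_flow) == len(self.condition) == n):
            raise ValueError("timeline arrays must share one length")
        if np.any(self.locomotion < 0) or np.any(self.visual_flow < 0):
            raise ValueError("speed traces must be nonnegative; direction lives on triggers")

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        return self.n_samples / self.frame_rate

    def trigger_times(self, kind: str) -> np.ndarray:
        return np.asarray(self.triggers.get(kind, np.empty(0)), dtype=float)


def concat_timelines(first: SessionTimeline, second: SessionTimeline) -> SessionTimeline:
    """Concatenate two timelines recorded back to back on one clock.

    Trigger times of the second timeline are offset by the duration of the
    first.  Frame rates must match.
    """
    if first.frame_rate != second.frame_rate:
        raise ValueError("frame rates differ")
    off = first.duration
    triggers = {k: np.asarray(v, dtype=float).copy() for k, v in first.triggers.items()}
    for k, v in second.triggers.items():
        shifted = np.asarray(v, dtype=float) + off
        triggers[k] = np.sort(np.concatenate([triggers.get(k, np.empty(0)), shifted]))
    return SessionTimeline(
        time=np.concatenate([first.time, second.time + off]),
        locomotion=np.concatenate([first.locomotion, second.locomotion]),
        visual_flow=np.concatenate([first.visual_flow, second.visual_flow]),
        condition=np.concatenate([first.condition, second.condition]),
        triggers=triggers,
        frame_rate=first.frame_rate,
    )


@dataclass
class RoiSet:
    """Per-ROI raw fluorescence plus geometry/QC attributes.

    raw_f is (n_rois, n_frames); label_image is an optional 2-D integer
    label image whose positive labels index into roi_ids.
    """

    raw_f: np.ndarray
    frame_rate: float
    roi_ids: np.ndarray = None
    label_image: np.ndarray = None

    def __post_init__(self):
        self.raw_f = np.atleast_2d(np.asarray(self.raw_f, dtype=float))
        if self.roi_ids is None:
            self.roi_ids = np.arange(1, self.raw_f.shape[0] + 1)
        self.roi_ids = np.asarray(self.roi_ids)

    @property
    def n_rois(self) -> int:
        return self.raw_f.shape[0]

    @property
    def n_frames(self) -> int:
        return self.raw_f.shape[1]


@dataclass
class Session:
    """One recording: timeline + ROI fluorescence (+ pupil, opto, metadata)."""

    timeline: SessionTimeline
    rois: RoiSet
    pupil_diameter: np.ndarray = None
    blink_mask: np.ndarray = None
    laser_on: np.ndarray = None
    opto_train_times: np.ndarray = None
    mouse_id: str = "m00"
    site_id: str = "s00"
    scheme: str = "LC"          # dataset scheme: LC (axons) or V1 (somata)
    seed: int = 0
    config_json: str = "{}"

    def config_dict(self) -> dict:
        return json.loads(self.config_json)
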