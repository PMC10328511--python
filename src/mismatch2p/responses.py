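"""Trial responses, visuomotor error, locomotion modulation, cell typing.

The quantities computed here are the core readouts of the closed-loop
visuomotor paradigm:

* **Trial response** — mean ΔF/F over a response window minus the mean
  over a pre-trigger baseline window; window placements differ between
  the fast axonal (LC, 60 Hz) and slower somatic (V1, 15 Hz) datasets.
* **Sham correction** — the average response at state-matched random
  triggers is subtracted from the stimulus response, removing
  behavior-conditioned baseline drift.
* **|Error| and Δ|Error|** — the unsigned difference between locomotion
  speed and gain-scaled visual-flow speed, and its stimulus-evoked change
  relative to the 1 s pre-stimulus mean.  Under closed-loop coupling
  |Error| is identically zero outside mismatch windows, so the Δ|Error|
  of a mismatch equals the locomotion speed during the halt.
* **LMI** — locomotion modulation index
  (R_loco − R_stat)/√(R_loco² + R_stat²) ∈ [−√2, √2], the normalized gain
  locomotion applies to a visual response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DEFAULTS
from .session import SessionTimeline


@dataclass(frozen=True)
class WindowSpec:
    """Baseline and response windows in seconds relative to the trigger."""

    baseline: tuple
    response: tuple

    def __post_init__(self):
        for name in ("baseline", "response"):
            lo, hi = getattr(self, name)
            if hi <= lo:
                raise ValueError(f"{name} window must have end > start")


@dataclass
class ResponseEstimate:
    """Trial-averaged, sham-corrected response with the ≥3-trial validity rule."""

    mean_response: float
    n_trials: int
    sham_mean: float = 0.0

    @property
    def valid(self) -> bool:
        return self.n_trials >= DEFAULTS["min_valid_trials"]

    @property
    def corrected(self) -> float:
        return self.mean_response - self.sham_mean


@dataclass
class LmiRecord:
    """Locomotion modulation index of one unit's visual response."""

    r_loco: float
    r_stat: float
    lmi: float
    defined: bool


def standard_windows(kind: str, dataset: str) -> WindowSpec:
    """The response/baseline windows for a stimulus kind and dataset scheme.

    LC mismatch and playback halt: response 0.66–1.66 s (the 1 s window
    beginning 40 frames at 60 Hz after onset); LC replay flow onset is
    delayed a further 400 ms for the slower stimulus ramp.  V1 stimuli:
    0.33–2.33 s.  Locomotion onsets use longer windows with earlier
    baselines.  Unknown kinds raise KeyError.
    """
    key = (kind, dataset)
    try:
        w = DEFAULTS["windows"][key]
    except KeyError:
        raise KeyError(f"no standard window for {key}") from None
    return WindowSpec(tuple(w["baseline"]), tuple(w["response"]))


def _win_slice(trigger: float, win: tuple, frame_rate: float, n: int):
    i0 = int(round((trigger + win[0]) * frame_rate))
    i1 = int(round((trigger + win[1]) * frame_rate))
    if i0 < 0 or i1 > n or i1 <= i0:
        return None
    return slice(i0, i1)


def trial_response(values: np.ndarray, frame_rate: float, trigger: float, spec: WindowSpec) -> float:
    """Baseline-subtracted response of one trial; NaN if a window leaves the trace."""
    values = np.asarray(values, dtype=float)
    sb = _win_slice(trigger, spec.baseline, frame_rate, len(values))
    sr = _win_slice(trigger, spec.response, frame_rate, len(values))
    if sb is None or sr is None:
        return np.nan
    return float(np.mean(values[sr]) - np.mean(values[sb]))


def trial_responses(values: np.ndarray, frame_rate: float, triggers, spec: WindowSpec) -> np.ndarray:
    """Vectorized trial_response over a list of triggers (NaN = dropped)."""
    return np.array([trial_response(values, frame_rate, t, spec) for t in np.asarray(triggers, dtype=float)])


def trial_response_matrix(values_2d: np.ndarray, frame_rate: float, triggers, spec: WindowSpec) -> np.ndarray:
    """Trial responses for many units at once: (n_units, n_triggers).

    Triggers whose windows leave the trace yield NaN columns.  Used for
    per-neuron sham correction, where the same large trigger set is
    evaluated against every unit's trace.
    """
    values_2d = np.atleast_2d(np.asarray(values_2d, dtype=float))
    n = values_2d.shape[1]
    triggers = np.asarray(triggers, dtype=float)
    out = np.full((values_2d.shape[0], len(triggers)), np.nan)
    for j, t in enumerate(triggers):
        sb = _win_slice(t, spec.baseline, frame_rate, n)
        sr = _win_slice(t, spec.response, frame_rate, n)
        if sb is None or sr is None:
            continue
        out[:, j] = values_2d[:, sr].mean(axis=1) - values_2d[:, sb].mean(axis=1)
    return out


def averaged_response(trial_values, sham_values=None) -> ResponseEstimate:
    """Trial average with sham subtraction and the ≥3-valid-trial rule.

    NaN trials (out-of-range windows) are dropped before counting.  When
    no state criterion applies, pass sham_values=None and the sham mean
    is zero.
    """
    tv = np.asarray(trial_values, dtype=float)
    tv = tv[np.isfinite(tv)]
    sham_mean = 0.0
    if sham_values is not None:
        sv = np.asarray(sham_values, dtype=float)
        sv = sv[np.isfinite(sv)]
        if sv.size:
            sham_mean = float(np.mean(sv))
    mean = float(np.mean(tv)) if tv.size else np.nan
    return ResponseEstimate(mean_response=mean, n_trials=int(tv.size), sham_mean=sham_mean)


def abs_error_trace(timeline: SessionTimeline, gain: float = None) -> np.ndarray:
    """|Error|(t) = |locomotion(t) − visual_flow(t)/gain| in cm/s.

    Flow is stored in locomotion-equivalent units, so with the default
    gain of 1 this is the plain absolute difference; a constant coupling
    gain rescales flow back into locomotion units first.
    """
    if gain is None:
        gain = DEFAULTS["coupling_gain"]
    if gain <= 0:
        raise ValueError("gain must be positive")
    return np.abs(timeline.locomotion - timeline.visual_flow / gain)


def delta_abs_error(
    abs_error: np.ndarray,
    frame_rate: float,
    trigger: float,
    response_window: tuple,
    shift: float = DEFAULTS["delta_error_shift_s"],
    pre_window: tuple = (-1.0, 0.0),
) -> float:
    """Stimulus-evoked change in unsigned visuomotor error, cm/s.

    Mean |Error| over a window equal in length to the ΔF/F response
    window but shifted ``shift`` (0.66 s) earlier, minus the mean over
    the 1 s pre-stimulus window.  NaN if either window leaves the trace.
    """
    err_win = (response_window[0] - shift, response_window[1] - shift)
    n = len(abs_error)
    s_err = _win_slice(trigger, err_win, frame_rate, n)
    s_pre = _win_slice(trigger, pre_window, frame_rate, n)
    if s_err is None or s_pre is None:
        return np.nan
    return float(np.mean(abs_error[s_err]) - np.mean(abs_error[s_pre]))


def lmi(r_loco: float, r_stat: float, eps: float = 1e-9) -> LmiRecord:
    """Locomotion modulation index (R_loco − R_stat)/√(R_loco² + R_stat²).

    Antisymmetric in its arguments and invariant to positive rescaling;
    bounded by ±√2.  Flagged undefined when both responses are ≈ 0
    (denominator below ``eps``), mirroring the 0/0 guard needed on weakly
    responsive units.
    """
    denom = float(np.hypot(r_loco, r_stat))
    if not np.isfinite(denom) or denom < eps:
        return LmiRecord(r_loco, r_stat, np.nan, defined=False)
    return LmiRecord(r_loco, r_stat, (r_loco - r_stat) / denom, defined=True)


def lmi_by_speed_bin(
    trial_values: np.ndarray,
    trial_speeds: np.ndarray,
    r_stat: float,
    bins=DEFAULTS["speed_bins_cmps"],
    min_trials: int = DEFAULTS["min_valid_trials"],
) -> pd.DataFrame:
    """LMI per locomotion-speed bin against a common stationary response.

    Bins are left-open/right-closed — (1, 5], (5, 10], (10, ∞) cm/s by
    default — so a boundary speed falls in the lower bin.  Bins with
    fewer than ``min_trials`` trials are flagged invalid.
    """
    tv = np.asarray(trial_values, dtype=float)
    ts = np.asarray(trial_speeds, dtype=float)
    rows = []
    for lo, hi in bins:
        in_bin = (ts > lo) & (ts <= hi)
        vals = tv[in_bin & np.isfinite(tv)]
        n = int(vals.size)
        r_loco = float(np.mean(vals)) if n else np.nan
        rec = lmi(r_loco, r_stat) if n >= min_trials else LmiRecord(r_loco, r_stat, np.nan, False)
        rows.append(
            {
                "bin_lo": lo,
                "bin_hi": hi,
                "n_trials": n,
                "r_loco": r_loco,
                "lmi": rec.lmi,
                "valid": n >= min_trials and rec.defined,
            }
        )
    return pd.DataFrame(rows)


def normalize_speed_threshold(speed: np.ndarray, reference_p95: float, nominal: float) -> float:
    """Rescale a locomotion threshold by this trace's 95th speed percentile.

    Datasets acquired with different speed measurements are made
    comparable by scaling nominal thresholds with
    p95(this trace)/reference_p95.
    """
    p95 = float(np.percentile(np.asarray(speed, dtype=float), 95))
    if p95 <= 0:
        raise ValueError("95th percentile of speed is zero; cannot normalize")
    if reference_p95 <= 0:
        raise ValueError("reference p95 must be positive")
    return nominal * p95 / reference_p95


def classify_neurons(
    closed_onset: np.ndarray,
    open_onset: np.ndarray,
    percentiles: tuple = DEFAULTS["class_percentiles"],
) -> np.ndarray:
    """Functional cell classes from closed−open locomotion-onset responses.

    The per-neuron difference between locomotion-onset responses in
    closed loop (flow concurrent with locomotion) and open loop is split
    at its dataset-wide 33rd/66th percentiles (linear interpolation):
    below the 33rd → NPE, above the 66th → PPE, otherwise (including
    exact ties at a boundary) → other.
    """
    closed_onset = np.asarray(closed_onset, dtype=float)
    open_onset = np.asarray(open_onset, dtype=float)
    if closed_onset.size < 3:
        raise ValueError("need at least 3 neurons to form percentile classes")
    diff = closed_onset - open_onset
    lo, hi = np.percentile(diff, percentiles)
    out = np.full(diff.shape, "other", dtype=object)
    out[diff < lo] = "NPE"
    out[diff > hi] = "PPE"
    return out


def axon_density(
    segment_lengths_per_image: list,
    image_area_um2: float,
    threshold: float = DEFAULTS["axon_density_threshold_um_per_um2"],
) -> tuple[float, str]:
    """Axon density (µm fiber per µm² cortex) and the expression class.

    ``segment_lengths_per_image`` is one list of traced segment lengths
    per image (conventionally four images per mouse); densities are
    averaged across images.  Class is ``high`` iff density ≥ threshold
    (boundary inclusive).
    """
    if image_area_um2 <= 0:
        raise ValueError("image area must be positive")
    densities = [float(np.sum(lengths)) / image_area_um2 for lengths in segment_lengths_per_image]
    density = float(np.mean(densities)) if densities else 0.0
    return density, ("high" if density >= threshold else "low")


def detect_blinks(
    diameter: np.ndarray,
    frame_rate: float,
    z_threshold: float = 4.0,
    derivative_threshold: float = 5.0,
    pad_s: float = 0.1,
) -> np.ndarray:
    """Default blink mask: robust diameter outliers or derivative spikes.

    A sample is flagged when its robust z-score (median/MAD) exceeds
    ``z_threshold`` or the per-second diameter derivative exceeds
    ``derivative_threshold`` robust SDs; flags are padded by ``pad_s``
    on both sides.  Intentionally simple — callers with a real eye
    camera should supply their own mask.
    """
    diameter = np.asarray(diameter, dtype=float)
    med = np.median(diameter)
    mad = np.median(np.abs(diameter - med)) * 1.4826
    mask = np.zeros(diameter.shape, dtype=bool)
    if mad > 0:
        mask |= np.abs(diameter - med) / mad > z_threshold
    dd = np.abs(np.diff(diameter, prepend=diameter[0])) * frame_rate
    dmad = np.median(np.abs(dd - np.median(dd))) * 1.4826
    if dmad > 0:
        mask |= dd > np.median(dd) + derivative_threshold * dmad
    pad = int(round(pad_s * frame_rate))
    if pad and mask.any():
        idx = np.flatnonzero(mask)
        for i in idx:
            mask[max(0, i - pad): i + pad + 1] = True
    return mask


def pupil_response(
    diameter: np.ndarray,
    frame_rate: float,
    triggers,
    blink_mask: np.ndarray = None,
    response_window: tuple = (0.0, 3.0),
    baseline_window: tuple = (-1.0, 0.0),
) -> ResponseEstimate:
    """Trial-averaged z-scored pupil dilation, excluding blink trials.

    The diameter trace is z-scored against its whole-trace mean and SD;
    each trial's baseline (mean over [−1, 0] s) is subtracted; trials
    whose baseline-to-response span overlaps any blink sample are
    dropped.
    """
    diameter = np.asarray(diameter, dtype=float)
    sd = float(np.std(diameter))
    if sd == 0:
        raise ValueError("constant pupil trace cannot be z-scored")
    z = (diameter - np.mean(diameter)) / sd
    spec = WindowSpec(baseline_window, response_window)
    vals = []
    for t in np.asarray(triggers, dtype=float):
        if blink_mask is not None:
            s = _win_slice(t, (baseline_window[0], response_window[1]), frame_rate, len(z))
            if s is None or np.any(np.asarray(blink_mask, dtype=bool)[s]):
                continue
        vals.append(trial_response(z, frame_rate, t, spec))
    return averaged_response(vals)
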