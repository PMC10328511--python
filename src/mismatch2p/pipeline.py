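"""End-to-end analyses: simulate → preprocess → events → responses → stats.

Two canonical pipelines:

* **LC (axonal)** — per session: ΔF/F + QC + FoV pooling, trial
  classification, sham-corrected responses to mismatches (by locomotion
  state), playback halts and replay flow onsets while stationary, with
  the matched Δ|Error| per condition; across sessions: the
  response-vs-speed regression of mismatch responses.
* **V1 (somatic, plasticity)** — per experiment arm: per-neuron LMI for
  each flow direction before and after the stimulation epoch,
  hierarchical-bootstrap inference on ΔLMI, functional cell typing from
  locomotion-onset responses, and the post-epoch speed-bin LMI slope.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import events, responses, roi, stats
from .config import DEFAULTS
from .session import CONDITION_CODES, Session
from .synth.v1 import V1Experiment


def _condition_range(timeline, label: str) -> tuple:
    """Time extent (s) of the first contiguous run of a condition."""
    code = CONDITION_CODES[label]
    idx = np.flatnonzero(timeline.condition == code)
    if idx.size == 0:
        raise ValueError(f"no samples with condition {label}")
    return idx[0] / timeline.frame_rate, (idx[-1] + 1) / timeline.frame_rate


def preprocess_lc_session(session: Session, snr_screen: bool = True) -> roi.DffTrace:
    """ΔF/F per axon ROI, SNR screen, 10 Hz low-pass, pooled FoV trace.

    ``snr_screen=False`` pools every ROI — useful for null sessions
    generated without any calcium signal, which the screen would
    (correctly) empty out.
    """
    fr = session.rois.frame_rate
    kept = []
    for f in session.rois.raw_f:
        d = roi.compute_dff(f, fr)
        if not snr_screen or roi.activity_snr(d)[1]:
            kept.append(d)
    if not kept:
        raise ValueError("no ROI passed the SNR screen")
    return roi.lowpass_and_pool(kept)


def _sham_corrected(pooled, tl, trig_times, states, criterion, spec, abs_err,
                    cond_label, n_sham, rng):
    """ResponseEstimate + mean Δ|Error| for one (stimulus, state) cell."""
    sel = [t for t, s in zip(trig_times, states) if events.state_matches(s, criterion)]
    vals = responses.trial_responses(pooled.values, pooled.frame_rate, sel, spec)
    rng_lo, rng_hi = _condition_range(tl, cond_label)
    sham_times = events.draw_sham_triggers(
        n_sham, (rng_lo, rng_hi), criterion, tl.locomotion, tl.frame_rate,
        scheme="LC", rng=rng, real_triggers=np.asarray(trig_times))
    sham_vals = responses.trial_responses(pooled.values, pooled.frame_rate, sham_times, spec)
    est = responses.averaged_response(vals, sham_vals)
    derr = [responses.delta_abs_error(abs_err, tl.frame_rate, t, spec.response) for t in sel]
    derr = np.asarray(derr, dtype=float)
    speeds = [np.mean(tl.locomotion[int(t * tl.frame_rate):int((t + 1) * tl.frame_rate)]) for t in sel]
    return est, float(np.nanmean(derr)) if derr.size else np.nan, \
        float(np.mean(speeds)) if speeds else np.nan


def analyze_lc_session(session: Session, n_sham: int = DEFAULTS["n_sham_lc"], seed=0,
                       snr_screen: bool = True) -> pd.DataFrame:
    """Sham-corrected FoV responses per stimulus condition and state.

    Conditions: mismatch × {stationary, slow, fast}, playback halt
    (stationary), replay flow onset (stationary).  Columns include the
    matched Δ|Error| so the response-vs-error relation can be read off
    directly.
    """
    rng = np.random.default_rng(seed)
    tl = session.timeline
    fr = tl.frame_rate
    pooled = preprocess_lc_session(session, snr_screen=snr_screen)
    abs_err = responses.abs_error_trace(tl)

    jobs = [
        ("mismatch", "stationary", "closed_loop", "mismatch"),
        ("mismatch", "slow", "closed_loop", "mismatch"),
        ("mismatch", "fast", "closed_loop", "mismatch"),
        ("playback_halt", "stationary", "open_loop_replay", "playback_halt"),
    ]
    rows = []
    for kind, criterion, cond_label, window_kind in jobs:
        trig = tl.trigger_times(kind)
        states = [events.classify_trial_state(tl.locomotion, fr, t, "LC") for t in trig]
        spec = responses.standard_windows(window_kind, "LC")
        est, derr, speed = _sham_corrected(pooled, tl, trig, states, criterion, spec,
                                           abs_err, cond_label, n_sham, rng)
        rows.append({"stimulus": kind, "state": criterion, "n_trials": est.n_trials,
                     "valid": est.valid, "response": est.corrected,
                     "uncorrected": est.mean_response, "sham": est.sham_mean,
                     "delta_abs_error": derr, "mean_speed": speed})

    # flow onsets during replay, detected from the flow trace itself
    lo, hi = _condition_range(tl, "open_loop_replay")
    i0, i1 = int(lo * fr), int(hi * fr)
    flow_onsets = events.detect_onsets(tl.visual_flow[i0:i1], fr) + lo
    states = [events.classify_trial_state(tl.locomotion, fr, t, "LC") for t in flow_onsets]
    spec = responses.standard_windows("flow_onset_open_loop", "LC")
    for criterion in ("stationary", "locomotion"):
        est, derr, speed = _sham_corrected(pooled, tl, flow_onsets, states, criterion, spec,
                                           abs_err, "open_loop_replay", n_sham, rng)
        rows.append({"stimulus": "flow_onset_replay", "state": criterion,
                     "n_trials": est.n_trials, "valid": est.valid,
                     "response": est.corrected, "uncorrected": est.mean_response,
                     "sham": est.sham_mean, "delta_abs_error": derr, "mean_speed": speed})
    out = pd.DataFrame(rows)
    out.insert(0, "site_id", session.site_id)
    out.insert(0, "mouse_id", session.mouse_id)
    return out


def analyze_lc_dataset(sessions: list, n_sham: int = DEFAULTS["n_sham_lc"],
                       n_boot: int = DEFAULTS["n_boot"], seed=0,
                       snr_screen: bool = True) -> dict:
    """Per-FoV condition table plus the mismatch response-vs-speed slope.

    The slope regresses valid per-FoV mismatch responses on the mean
    locomotion speed of their state bin (stationary/slow/fast),
    bootstrapping FoVs then points.
    """
    rng = np.random.default_rng(seed)
    tables = [analyze_lc_session(s, n_sham, seed=rng.integers(2**31), snr_screen=snr_screen)
              for s in sessions]
    table = pd.concat(tables, ignore_index=True)
    mm = table[(table.stimulus == "mismatch") & table.valid & np.isfinite(table.mean_speed)]
    if len(mm) >= 4 and mm.mean_speed.nunique() > 1:
        dist, p_neg = stats.hier_boot_slope(mm.mean_speed.to_numpy(), mm.response.to_numpy(),
                                            mm.site_id.to_numpy(), n_boot=n_boot,
                                            seed=int(rng.integers(2**31)))
        slope = float(np.mean(dist.stats))
        p_pos = stats._floor_p(float(np.mean(dist.stats < 0)), n_boot)
    else:
        slope, p_neg, p_pos = np.nan, np.nan, np.nan
    return {"table": table, "speed_slope": slope,
            "p_slope_positive": p_pos, "p_slope_negative": p_neg}


# ---------------------------------------------------------------------------
# V1 plasticity pipeline
# ---------------------------------------------------------------------------

def _dff_matrix(session: Session) -> np.ndarray:
    fr = session.rois.frame_rate
    return np.stack([roi.compute_dff(f, fr).values for f in session.rois.raw_f])


def epoch_lmi(session: Session, direction: str, n_sham: int = DEFAULTS["n_sham_v1"],
              seed=0, dff: np.ndarray = None) -> pd.DataFrame:
    """Per-neuron LMI for one flow direction in one epoch.

    Open-loop fixed-speed stimulus trials are classified by mean
    locomotion speed during the 1 s stimulus (V1 scheme); locomotion and
    stationary responses are sham-corrected against 1000 state-matched
    random triggers and combined into the LMI.  Per-trial values and
    speeds are returned for downstream speed-bin analyses.
    """
    rng = np.random.default_rng(seed)
    tl = session.timeline
    fr = tl.frame_rate
    if dff is None:
        dff = _dff_matrix(session)
    trig = tl.trigger_times(f"flow_onset_{direction}")
    spec = responses.standard_windows("stimulus", "V1")
    states = [events.classify_trial_state(tl.locomotion, fr, t, "V1") for t in trig]
    speeds = np.array([np.mean(tl.locomotion[int(t * fr):int((t + 1) * fr)]) for t in trig])
    vals = responses.trial_response_matrix(dff, fr, trig, spec)   # (n_neurons, n_trials)

    cond_rng = _condition_range(tl, "open_loop_fixed")
    sham_means = {}
    for criterion in ("locomotion", "stationary"):
        sham_t = events.draw_sham_triggers(n_sham, cond_rng, criterion, tl.locomotion, fr,
                                           scheme="V1", rng=rng, real_triggers=trig)
        sv = responses.trial_response_matrix(dff, fr, sham_t, spec)
        sham_means[criterion] = np.nanmean(sv, axis=1) if sv.size else np.zeros(dff.shape[0])

    loco_mask = np.array([s == "locomotion" for s in states])
    stat_mask = np.array([s == "stationary" for s in states])
    rows = []
    for i in range(dff.shape[0]):
        lv = vals[i, loco_mask]
        sv = vals[i, stat_mask]
        lv, sv = lv[np.isfinite(lv)], sv[np.isfinite(sv)]
        r_loco = float(np.mean(lv)) - sham_means["locomotion"][i] if lv.size else np.nan
        r_stat = float(np.mean(sv)) - sham_means["stationary"][i] if sv.size else np.nan
        ok = lv.size >= DEFAULTS["min_valid_trials"] and sv.size >= DEFAULTS["min_valid_trials"]
        rec = responses.lmi(r_loco, r_stat) if ok else responses.LmiRecord(r_loco, r_stat, np.nan, False)
        rows.append({"neuron": i, "direction": direction, "r_loco": r_loco, "r_stat": r_stat,
                     "lmi": rec.lmi, "valid": ok and rec.defined,
                     "n_loco": int(lv.size), "n_stat": int(sv.size)})
    extras = {"trial_values": vals, "trial_speeds": speeds,
              "sham_loco": sham_means["locomotion"]}
    return pd.DataFrame(rows), extras


def _onset_responses(session: Session, dff: np.ndarray) -> tuple:
    """Per-neuron locomotion-onset responses split by closed/open context."""
    tl = session.timeline
    fr = tl.frame_rate
    onsets = events.detect_onsets(tl.locomotion, fr)
    ctx = [tl.condition[int(t * fr)] for t in onsets]
    closed_t = [t for t, c in zip(onsets, ctx) if c == CONDITION_CODES["closed_loop"]]
    open_t = [t for t, c in zip(onsets, ctx) if c != CONDITION_CODES["closed_loop"]]
    spec = responses.standard_windows("locomotion_onset", "V1")
    closed_v = np.nanmean(responses.trial_response_matrix(dff, fr, closed_t, spec), axis=1) \
        if closed_t else np.full(dff.shape[0], np.nan)
    open_v = np.nanmean(responses.trial_response_matrix(dff, fr, open_t, spec), axis=1) \
        if open_t else np.full(dff.shape[0], np.nan)
    return closed_v, open_v


def classify_experiment_neurons(exp: V1Experiment, dff_pre: list = None) -> pd.DataFrame:
    """Functional classes from pre-epoch closed−open locomotion-onset
    responses, percentile thresholds taken dataset-wide."""
    if dff_pre is None:
        dff_pre = [_dff_matrix(s) for s in exp.pre]
    closed_all, open_all = [], []
    for session, dff in zip(exp.pre, dff_pre):
        c, o = _onset_responses(session, dff)
        closed_all.append(c)
        open_all.append(o)
    closed_v = np.concatenate(closed_all)
    open_v = np.concatenate(open_all)
    classes = responses.classify_neurons(closed_v, open_v)
    return pd.DataFrame({"neuron": np.arange(len(closed_v)),
                         "onset_closed": closed_v, "onset_open": open_v,
                         "predicted_class": classes})


def analyze_v1_experiment(exp: V1Experiment, n_sham: int = DEFAULTS["n_sham_v1"],
                          n_boot: int = DEFAULTS["n_boot"], seed=0,
                          classify: bool = True) -> dict:
    """ΔLMI inference per direction, cell typing, and the post-epoch
    speed-bin LMI slope for one experiment arm.

    Returns a dict with per-neuron tables (``lmi``), per-direction
    hierarchical-bootstrap results (``delta_lmi``), the predicted cell
    classes (``classes``), and the speed-bin slope record
    (``speed_bin``).
    """
    rng = np.random.default_rng(seed)
    dff_pre = [_dff_matrix(s) for s in exp.pre]
    dff_post = [_dff_matrix(s) for s in exp.post]

    lmi_rows, delta = [], {}
    speed_rows = {"x": [], "y": [], "site": []}
    for direction in ("NT", "TN"):
        site_tables = []
        for k, site in enumerate(exp.sites):
            pre, _ = epoch_lmi(exp.pre[k], direction, n_sham,
                               seed=rng.integers(2**31), dff=dff_pre[k])
            post, post_extras = epoch_lmi(exp.post[k], direction, n_sham,
                                          seed=rng.integers(2**31), dff=dff_post[k])
            merged = pre.merge(post, on="neuron", suffixes=("_pre", "_post"))
            merged["dlmi"] = merged.lmi_post - merged.lmi_pre
            merged["direction"] = direction
            merged["site_id"] = site
            # global row index into exp.neurons (sites are concatenated in order)
            offset = sum(d.shape[0] for d in dff_pre[:k])
            merged["neuron"] = merged["neuron"] + offset
            site_tables.append(merged)
            if direction == "NT":
                vals = post_extras["trial_values"]
                speeds = post_extras["trial_speeds"]
                sham_loco = post_extras["sham_loco"]
                for i in range(vals.shape[0]):
                    r_stat = post.r_stat.iloc[i]
                    if not np.isfinite(r_stat):
                        continue
                    bins = responses.lmi_by_speed_bin(vals[i] - sham_loco[i], speeds, r_stat)
                    for _, b in bins[bins.valid].iterrows():
                        in_bin = (speeds > b.bin_lo) & (speeds <= b.bin_hi)
                        speed_rows["x"].append(float(np.mean(speeds[in_bin])))
                        speed_rows["y"].append(b.lmi)
                        speed_rows["site"].append(site)
        merged = pd.concat(site_tables, ignore_index=True)
        lmi_rows.append(merged)
        ok = merged.valid_pre & merged.valid_post & np.isfinite(merged.dlmi)
        sample = stats.NestedSample(merged.dlmi[ok].to_numpy(), merged.site_id[ok].to_numpy())
        dist = stats.hier_boot(sample, n_boot=n_boot, seed=int(rng.integers(2**31)))
        delta[direction] = {
            "mean_dlmi": float(np.mean(sample.values)),
            "mean_lmi_pre": float(np.nanmean(merged.lmi_pre[ok])),
            "mean_lmi_post": float(np.nanmean(merged.lmi_post[ok])),
            "n_neurons": int(ok.sum()),
            "p_two_sided": stats.p_vs_zero(dist, "two-sided"),
            "p_negative": stats.p_vs_zero(dist, "less"),
        }
    lmi_table = pd.concat(lmi_rows, ignore_index=True)

    xs, ys, sids = speed_rows["x"], speed_rows["y"], speed_rows["site"]
    if len(xs) >= 4 and len(set(xs)) > 1:
        dist, p_neg = stats.hier_boot_slope(np.array(xs), np.array(ys), np.array(sids),
                                            n_boot=n_boot, seed=int(rng.integers(2**31)))
        speed_bin = {"slope": float(np.mean(dist.stats)), "p_negative": p_neg,
                     "n_points": len(xs)}
    else:
        speed_bin = {"slope": np.nan, "p_negative": np.nan, "n_points": len(xs)}

    classes = classify_experiment_neurons(exp, dff_pre) if classify else None
    return {"lmi": lmi_table, "delta_lmi": delta, "classes": classes,
            "speed_bin": speed_bin, "protocol": exp.protocol,
            "expression": exp.expression, "plasticity_applied": exp.plasticity_applied}
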