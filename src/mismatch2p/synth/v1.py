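"""Synthetic V1 layer-2/3 populations and the pre/post plasticity experiment.

Each neuron is a linear rate unit with a visual-flow response whose gain
during locomotion is g (the canonical locomotion gain, g > 1 on
average), a mismatch response, and locomotion-onset responses that
differ between closed- and open-loop context according to its
functional class (NPE / PPE / other).  An experiment runs two identical
epochs — closed-loop visuomotor coupling with mismatches and laser
trains, followed by open-loop fixed-speed flow stimuli in both
directions — separated by a plasticity step: when the protocol is
closed-loop optogenetic stimulation in a high-expression animal, the
nasotemporal locomotion gain is reduced by

    g → g · (1 − ρ · min(s, s_ref)/s_ref)

per trial locomotion speed s (s_ref = 20 cm/s), leaving temporonasal
and all stationary responses untouched.  Control and open-loop
protocols, and low-expression animals, leave every gain unchanged.
The plasticity step is instantaneous between epochs; the readout is
pre vs post, not a learning curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .. import events
from ..session import CONDITION_CODES, RoiSet, Session, concat_timelines
from .behavior import (SessionConfig, generate_locomotion_trace,
                       make_closed_loop, make_fixed_flow_timeline,
                       make_opto_train, schedule_events)
from .calcium import CalciumParams, calcium_kernel, simulate_fluorescence
from .pupil import generate_pupil_trace

PROTOCOLS = ("closed_loop_opto", "open_loop_opto", "control")

#: class-conditional parameter means: (visual_amp, mismatch_amp, onset_diff)
_CLASS_MEANS = {
    "NPE": (0.30, 0.80, -0.25),
    "other": (0.50, 0.30, 0.00),
    "PPE": (0.80, 0.10, +0.25),
}


@dataclass
class V1NeuronModel:
    """Generative parameters of one layer-2/3 neuron."""

    cell_class: str
    visual_amp: float            # rate units per unit flow drive
    mismatch_amp: float
    locomotion_gain: float       # g, multiplicative on visual response while running
    onset_amp_closed: float      # locomotion-onset response, closed loop
    onset_amp_open: float        # locomotion-onset response, open loop
    plasticity_rate: float = 0.6  # fractional NT-gain reduction at s >= s_ref
    response_cv: float = 0.35    # per-trial multiplicative response variability
    direction_pref: str = "none"
    mouse_id: str = "m00"
    site_id: str = "s00"

    def __post_init__(self):
        if self.locomotion_gain <= 0:
            raise ValueError("pre-plasticity gain must be positive")


def sample_v1_population(
    n_mice: int = 3,
    n_sites_per_mouse: int = 2,
    n_neurons_per_site: int = 30,
    g_mean: float = 1.6,
    g_sd: float = 0.15,
    plasticity_rate: float = 0.6,
    response_cv: float = 0.35,
    mouse_sd: float = 0.1,
    site_sd: float = 0.1,
    neuron_sd: float = 0.15,
    seed=0,
) -> list[V1NeuronModel]:
    """A nested population with balanced NPE/other/PPE thirds per site.

    Lognormal mouse/site/neuron multipliers on the response amplitudes
    provide the nested variance hierarchical inference relies on.
    """
    rng = np.random.default_rng(seed)
    classes = ["NPE", "other", "PPE"]
    pop = []
    for m in range(n_mice):
        m_eff = rng.lognormal(0, mouse_sd)
        for s in range(n_sites_per_mouse):
            s_eff = m_eff * rng.lognormal(0, site_sd)
            for i in range(n_neurons_per_site):
                cls = classes[i % 3]
                va, ma, od = _CLASS_MEANS[cls]
                n_eff = s_eff * rng.lognormal(0, neuron_sd)
                onset_base = 0.05 * n_eff
                diff = od * n_eff + rng.normal(0, 0.02)
                pop.append(
                    V1NeuronModel(
                        cell_class=cls,
                        visual_amp=va * n_eff,
                        mismatch_amp=ma * n_eff,
                        locomotion_gain=max(float(rng.normal(g_mean, g_sd)), 1.05),
                        onset_amp_closed=onset_base + diff / 2,
                        onset_amp_open=onset_base - diff / 2,
                        plasticity_rate=plasticity_rate,
                        response_cv=response_cv,
                        mouse_id=f"m{m:02d}",
                        site_id=f"m{m:02d}_s{s:02d}",
                    )
                )
    return pop


def population_frame(population: list[V1NeuronModel]) -> pd.DataFrame:
    """Ground-truth table of a population (one row per neuron)."""
    return pd.DataFrame(
        {
            "neuron": np.arange(len(population)),
            "mouse_id": [p.mouse_id for p in population],
            "site_id": [p.site_id for p in population],
            "cell_class": [p.cell_class for p in population],
            "visual_amp": [p.visual_amp for p in population],
            "mismatch_amp": [p.mismatch_amp for p in population],
            "locomotion_gain": [p.locomotion_gain for p in population],
            "onset_diff": [p.onset_amp_closed - p.onset_amp_open for p in population],
        }
    )


@dataclass
class V1Experiment:
    """Pre/post sessions (one pair per imaging site) plus ground truth.

    ``pre[k]`` and ``post[k]`` are the two epochs of site ``sites[k]``,
    each with its own behavior; ``neurons`` rows are ordered site by
    site in the same order, matching the concatenation of the per-site
    ROI sets.
    """

    pre: list
    post: list
    sites: list
    neurons: pd.DataFrame
    protocol: str
    expression: str
    plasticity_applied: bool
    config: SessionConfig = None


def _boxcar_onset_kernel(frame_rate: float) -> np.ndarray:
    """Sustained 3 s locomotion-onset response kernel with a 0.5 s ramp."""
    ramp = np.linspace(0, 1, max(int(0.5 * frame_rate), 1))
    hold = np.ones(int(2.5 * frame_rate))
    tail = np.linspace(1, 0, max(int(0.5 * frame_rate), 1))
    return np.concatenate([ramp, hold, tail])


def _epoch_session(
    population: list[V1NeuronModel],
    config: SessionConfig,
    protocol: str,
    expression: str,
    suppressed: bool,
    s_ref: float,
    closed_duration: float,
    open_duration: float,
    calcium: CalciumParams,
    seed,
) -> Session:
    """Simulate one epoch: closed-loop (mismatches + opto) then open-loop
    fixed-speed flow in both directions."""
    rng = np.random.default_rng(seed)
    fr = config.frame_rate

    cl_cfg = SessionConfig(**{**config.__dict__, "duration": closed_duration})
    loco_cl = generate_locomotion_trace(cl_cfg, seed=rng.integers(2**31))
    mm_times = schedule_events(closed_duration - config.mismatch_duration,
                               config.mismatch_interval_mean, config.mismatch_interval_sd,
                               seed=rng.integers(2**31), floor=config.interval_floor)
    closed = make_closed_loop(loco_cl, mm_times, cl_cfg)

    ol_cfg = SessionConfig(**{**config.__dict__, "duration": open_duration})
    loco_ol = generate_locomotion_trace(ol_cfg, seed=rng.integers(2**31))
    open_tl = make_fixed_flow_timeline(loco_ol, ol_cfg, seed=rng.integers(2**31))

    timeline = concat_timelines(closed, open_tl)
    n = timeline.n_samples
    speed = timeline.locomotion
    running = (speed > 4.0).astype(float)

    # laser trains: in the closed segment for closed-loop and control
    # protocols, in the open segment for the open-loop protocol
    opto_cfg = cl_cfg if protocol != "open_loop_opto" else ol_cfg
    seg_duration = closed_duration if protocol != "open_loop_opto" else open_duration
    seg_offset = 0.0 if protocol != "open_loop_opto" else closed_duration
    seg_loco = loco_cl if protocol != "open_loop_opto" else loco_ol
    laser_seg, train_times = make_opto_train(opto_cfg, duration=seg_duration,
                                             loco=seg_loco, seed=rng.integers(2**31))
    laser = np.zeros(n, dtype=np.uint8)
    i0 = int(round(seg_offset * fr))
    laser[i0 : i0 + len(laser_seg)] = laser_seg
    train_times = train_times + seg_offset
    timeline.triggers["opto_train"] = train_times

    n_neurons = len(population)
    g = np.array([p.locomotion_gain for p in population])
    rho = np.array([p.plasticity_rate for p in population])
    vamp = np.array([p.visual_amp for p in population])
    mamp = np.array([p.mismatch_amp for p in population])
    oc = np.array([p.onset_amp_closed for p in population])
    oo = np.array([p.onset_amp_open for p in population])
    cv = np.array([p.response_cv for p in population])

    def trial_factor():
        # independent per-neuron per-event response variability, floored at 0
        return np.clip(1.0 + cv * rng.standard_normal(n_neurons), 0.0, None)

    # per-sample speed-dependent gain suppression factor (NT only, post epoch)
    supp = np.minimum(speed, s_ref) / s_ref if suppressed else np.zeros(n)

    rate = np.zeros((n_neurons, n))
    stim_len = int(round(config.flow_stim_duration * fr))
    for d in ("NT", "TN"):
        for t in timeline.trigger_times(f"flow_onset_{d}"):
            j0 = int(round(t * fr))
            sl = slice(j0, min(j0 + stim_len, n))
            if d == "NT":
                g_eff = g[:, None] * (1.0 - rho[:, None] * supp[None, sl])
            else:
                g_eff = np.broadcast_to(g[:, None], (n_neurons, sl.stop - sl.start))
            m = 1.0 + (g_eff - 1.0) * running[None, sl]
            rate[:, sl] += vamp[:, None] * trial_factor()[:, None] * m
    mm_len = int(round(config.mismatch_duration * fr))
    for t in timeline.trigger_times("mismatch"):
        j0 = int(round(t * fr))
        rate[:, j0 : j0 + mm_len] += (mamp * trial_factor())[:, None]

    # locomotion-onset responses split by closed/open context
    kernel = _boxcar_onset_kernel(fr)
    for t in events.detect_onsets(speed, fr):
        j = int(round(t * fr))
        closed_ctx = timeline.condition[j] == CONDITION_CODES["closed_loop"]
        amp = oc if closed_ctx else oo
        seg = kernel[: n - j]
        rate[:, j : j + len(seg)] += (amp * trial_factor())[:, None] * seg[None, :]

    traces = np.empty((n_neurons, n))
    for i in range(n_neurons):
        traces[i] = simulate_fluorescence(rate[i], calcium, fr, seed=rng.integers(2**31))

    dilation = {"high": 3.0, "low": 0.6}.get(expression, 0.1)
    pupil, blink = generate_pupil_trace(timeline.duration, fr, opto_times=train_times,
                                        dilation_amp=dilation, seed=rng.integers(2**31))
    return Session(
        timeline=timeline,
        rois=RoiSet(traces, frame_rate=fr),
        pupil_diameter=pupil,
        blink_mask=blink,
        laser_on=laser,
        opto_train_times=train_times,
        mouse_id="multi",
        site_id="multi",
        scheme="V1",
        seed=int(seed),
        config_json=config.to_json(),
    )


def simulate_v1_experiment(
    config: SessionConfig,
    population: list[V1NeuronModel],
    protocol: str,
    expression: str = "high",
    closed_duration: float = 300.0,
    open_duration: float = 600.0,
    s_ref: float = 20.0,
    seed=0,
    calcium: CalciumParams = None,
) -> V1Experiment:
    """Two-epoch plasticity experiment under one protocol arm.

    Plasticity (the NT locomotion-gain reduction) is applied between
    epochs only for protocol ``closed_loop_opto`` in a high-expression
    animal; every other arm leaves the generative gains untouched, so a
    control experiment's post responses differ from pre only by fresh
    behavior and noise.
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}")
    if not population:
        raise ValueError("empty population")
    calcium = calcium or CalciumParams.jgcamp8m_like(noise_sd=1.0, amplitude=100.0)
    rng = np.random.default_rng(seed)
    applied = protocol == "closed_loop_opto" and expression == "high"
    common = dict(config=config, protocol=protocol, expression=expression,
                  s_ref=s_ref, closed_duration=closed_duration,
                  open_duration=open_duration, calcium=calcium)
    # one independent pre/post session pair per imaging site: behavior
    # is recorded per site, so site-level resampling downstream sees the
    # behavioral variability it needs to capture
    sites = list(dict.fromkeys(p.site_id for p in population))
    ordered = [p for s in sites for p in population if p.site_id == s]
    pre_sessions, post_sessions = [], []
    for s in sites:
        subpop = [p for p in ordered if p.site_id == s]
        pre = _epoch_session(subpop, suppressed=False, seed=rng.integers(2**31), **common)
        post = _epoch_session(subpop, suppressed=applied, seed=rng.integers(2**31), **common)
        pre.mouse_id = post.mouse_id = subpop[0].mouse_id
        pre.site_id = post.site_id = s
        pre_sessions.append(pre)
        post_sessions.append(post)
    return V1Experiment(pre=pre_sessions, post=post_sessions, sites=sites,
                        neurons=population_frame(ordered),
                        protocol=protocol, expression=expression,
                        plasticity_applied=applied, config=config)
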