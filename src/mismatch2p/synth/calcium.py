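"""Forward model from latent activity rate to raw fluorescence.

A linear rate→fluorescence model: the latent rate is convolved with a
difference-of-exponentials calcium kernel (normalized to unit peak),
scaled, and summed with a baseline, a linear drift, and white Gaussian
noise.  Two indicator presets are provided: a slow GCaMP6s-like kernel
for axonal sessions and a faster jGCaMP8m-like kernel for somatic
sessions.  No spiking discretization or saturation — linearity is what
the downstream estimators assume, and is sufficient to exercise all of
them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class CalciumParams:
    """Kernel time constants, baseline, drift and noise of one indicator."""

    kernel_rise: float = 0.05     # s
    kernel_decay: float = 0.6     # s
    baseline_f: float = 100.0     # arbitrary fluorescence units
    noise_sd: float = 1.0         # fluorescence units
    drift_slope: float = 0.0      # fluorescence units / s
    amplitude: float = 1.0        # fluorescence units per unit rate

    def __post_init__(self):
        if not (self.kernel_decay > self.kernel_rise > 0):
            raise ValueError("need decay > rise > 0")
        if self.baseline_f <= 0:
            raise ValueError("baseline_F must be positive")

    @classmethod
    def gcamp6s_like(cls, **kw) -> "CalciumParams":
        return cls(kernel_rise=0.18, kernel_decay=1.0, **kw)

    @classmethod
    def jgcamp8m_like(cls, **kw) -> "CalciumParams":
        return cls(kernel_rise=0.04, kernel_decay=0.25, **kw)


def calcium_kernel(params: CalciumParams, frame_rate: float, length_s: float = None) -> np.ndarray:
    """Difference-of-exponentials kernel normalized to unit peak.

    k(t) = exp(−t/decay) − exp(−t/rise), peaking at
    t* = rise·decay/(decay−rise)·ln(decay/rise), truncated at
    ``length_s`` (default 6 decay constants).
    """
    if length_s is None:
        length_s = 6.0 * params.kernel_decay
    t = np.arange(0, length_s, 1.0 / frame_rate)
    k = np.exp(-t / params.kernel_decay) - np.exp(-t / params.kernel_rise)
    peak = k.max()
    if peak <= 0:
        raise ValueError("degenerate kernel")
    return k / peak


def simulate_fluorescence(
    rate: np.ndarray,
    params: CalciumParams,
    frame_rate: float,
    seed=0,
) -> np.ndarray:
    """Raw fluorescence F = baseline + drift·t + amp·(kernel ⊛ rate) + noise.

    The rate may dip below zero (signalling activity below baseline);
    rectification, if wanted, is the caller's choice upstream.
    """
    rate = np.asarray(rate, dtype=float)
    rng = np.random.default_rng(seed)
    k = calcium_kernel(params, frame_rate)
    driven = np.convolve(rate, k)[: len(rate)] * params.amplitude / frame_rate
    t = np.arange(len(rate)) / frame_rate
    noise = rng.normal(0.0, params.noise_sd, size=len(rate)) if params.noise_sd > 0 else 0.0
    return params.baseline_f + params.drift_slope * t + driven + noise
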