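"""Synthetic pupil-diameter traces.

Pupil diameter is generated directly as a slow noisy trace with
dilation transients locked to optogenetic trains (amplitude scaled by
axonal expression level) and occasional blink artifacts, recorded in a
parallel blink mask.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d


def generate_pupil_trace(
    duration: float,
    frame_rate: float,
    opto_times=(),
    dilation_amp: float = 1.0,
    baseline: float = 50.0,
    noise_sd: float = 1.0,
    blink_rate_hz: float = 0.02,
    seed=0,
) -> tuple[np.ndarray, np.ndarray]:
    """(diameter, blink_mask) at ``frame_rate``.

    Each opto train adds a ~2 s dilation transient of amplitude
    ``dilation_amp`` (arbitrary units; scale with expression level).
    Blinks are short dropouts flagged True in the mask.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * frame_rate))
    t = np.arange(n) / frame_rate
    diam = baseline + gaussian_filter1d(rng.normal(0, noise_sd, n), frame_rate)
    kernel_t = np.arange(0, 6.0, 1.0 / frame_rate)
    kernel = (np.exp(-kernel_t / 2.0) - np.exp(-kernel_t / 0.4))
    kernel /= kernel.max()
    drive = np.zeros(n)
    for ot in np.asarray(opto_times, dtype=float):
        i = int(round(ot * frame_rate))
        if 0 <= i < n:
            drive[i] += 1.0
    diam = diam + dilation_amp * np.convolve(drive, kernel)[:n]
    blink = np.zeros(n, dtype=bool)
    n_blinks = rng.poisson(blink_rate_hz * duration)
    for i in rng.integers(0, max(n - 10, 1), size=n_blinks):
        width = int(rng.integers(2, int(0.3 * frame_rate) + 3))
        diam[i : i + width] = baseline * 0.2
        blink[i : i + width] = True
    return diam, blink
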