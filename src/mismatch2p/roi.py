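"""ROI quality control and ΔF/F processing.

Raw per-ROI fluorescence is drift-corrected with a running 8th-percentile
baseline (1000-frame centered window, shrinking at the edges) and
normalized by the median of the raw trace:

    ΔF/F(t) = (F(t) − F0(t)) / median(F)

Axon-segment ROIs are additionally screened by morphology — a circularity
index CI = 4π·area/perimeter² above 0.14 or an area below 150 px excludes
the ROI — and by a spectral signal-to-noise ratio: mean periodogram power
in 0.05–1 Hz (signal) over 3–8 Hz (noise), excluded below 10.  Surviving
axon ROIs in one field of view are low-pass filtered at 10 Hz (zero-phase
Butterworth) and averaged into a single FoV trace.

Perimeter convention: length of the marching-squares contour of the mask
(``skimage.measure.find_contours`` at level 0.5 on a zero-padded mask).
The CI threshold is coupled to this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from skimage import measure

from .config import DEFAULTS


@dataclass
class RoiGeometry:
    """Morphological descriptors of one labelled region."""

    label: int
    area: float          # pixels
    perimeter: float     # contour length, pixels
    circularity: float   # 4*pi*area/perimeter**2

    def __post_init__(self):
        if self.area <= 0 or self.perimeter <= 0:
            raise ValueError("area and perimeter must be positive")


@dataclass
class DffTrace:
    """A ΔF/F trace with its frame rate and QC record."""

    values: np.ndarray
    frame_rate: float
    qc: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in ΔF/F trace")


def running_percentile(x: np.ndarray, window: int, percentile: float) -> np.ndarray:
    """Centered running percentile with window shrinkage at the edges."""
    s = pd.Series(np.asarray(x, dtype=float))
    return s.rolling(window=window, center=True, min_periods=1).quantile(
        percentile / 100.0, interpolation="linear"
    ).to_numpy()


def compute_dff(
    f: np.ndarray,
    frame_rate: float,
    window: int = DEFAULTS["dff_window_frames"],
    percentile: float = DEFAULTS["dff_percentile"],
    median_of_raw: bool = True,
) -> DffTrace:
    """Drift-corrected, median-normalized ΔF/F of a raw fluorescence trace.

    Parameters
    ----------
    f : raw fluorescence, arbitrary units
    window : running-percentile window in frames (centered, shrinking edges)
    percentile : baseline percentile of F within the window
    median_of_raw : normalize by the median of the raw trace (default);
        if False, by the median of the drift-corrected trace

    The result is invariant to multiplicative rescaling of ``f``.
    """
    f = np.asarray(f, dtype=float)
    if f.size < 2:
        raise ValueError("trace too short for ΔF/F")
    f0 = running_percentile(f, window, percentile)
    denom = float(np.median(f if median_of_raw else f - f0))
    if denom <= 0:
        raise ValueError("nonpositive median fluorescence: degenerate trace")
    return DffTrace((f - f0) / denom, frame_rate)


def circularity_index(mask: np.ndarray) -> float:
    """CI = 4π·area/perimeter² of a binary region.

    Perimeter is the summed length of the marching-squares contour(s) of
    the mask; this convention reads CI ≈ 1 for rasterized discs and small
    values for thin elongated regions, and is the one the 0.14 threshold
    is calibrated against.  Translation invariant.
    """
    mask = np.asarray(mask).astype(bool)
    area = int(mask.sum())
    if area == 0:
        raise ValueError("empty mask")
    perim = mask_perimeter(mask)
    if perim == 0:  # single pixel: contour length 2*sqrt(2) from 4 segments
        raise ValueError("degenerate region with zero-length contour")
    return 4.0 * np.pi * area / perim**2


def mask_perimeter(mask: np.ndarray) -> float:
    """Marching-squares contour length of a binary mask (padded, level 0.5)."""
    padded = np.pad(np.asarray(mask, dtype=float), 1)
    total = 0.0
    for contour in measure.find_contours(padded, 0.5):
        total += float(np.sum(np.hypot(*np.diff(contour, axis=0).T)))
    return total


def roi_geometries(label_image: np.ndarray) -> list[RoiGeometry]:
    """Compute RoiGeometry for every positive label in a label image."""
    out = []
    for p in measure.regionprops(np.asarray(label_image)):
        mask = p.image
        perim = mask_perimeter(mask)
        out.append(
            RoiGeometry(
                label=int(p.label),
                area=float(p.area),
                perimeter=perim,
                circularity=4.0 * np.pi * p.area / perim**2,
            )
        )
    return out


def morphology_filter(
    geometries: list[RoiGeometry],
    ci_max: float = DEFAULTS["circularity_max"],
    area_min: float = DEFAULTS["area_min_px"],
) -> pd.DataFrame:
    """Keep ROIs with CI ≤ ci_max and area ≥ area_min.

    Returns a DataFrame (label, area, perimeter, circularity, kept,
    reasons) where ``reasons`` lists which thresholds failed.
    """
    rows = []
    for g in geometries:
        reasons = []
        if g.circularity > ci_max:
            reasons.append("circularity")
        if g.area < area_min:
            reasons.append("area")
        rows.append(
            {
                "label": g.label,
                "area": g.area,
                "perimeter": g.perimeter,
                "circularity": g.circularity,
                "kept": not reasons,
                "reasons": ";".join(reasons),
            }
        )
    return pd.DataFrame(rows, columns=["label", "area", "perimeter", "circularity", "kept", "reasons"])


def activity_snr(
    dff: DffTrace,
    signal_band: tuple = DEFAULTS["snr_signal_band_hz"],
    noise_band: tuple = DEFAULTS["snr_noise_band_hz"],
    threshold: float = DEFAULTS["snr_threshold"],
) -> tuple[float, bool]:
    """Spectral SNR of a ΔF/F trace and the keep decision.

    SNR = mean periodogram power over the signal band / mean over the
    noise band, bands taken over strictly interior frequency bins of the
    mean-subtracted trace.  Keep iff SNR ≥ threshold.
    """
    fs = dff.frame_rate
    if fs / 2 <= noise_band[1]:
        raise ValueError("noise band reaches Nyquist; frame rate too low")
    x = dff.values - np.mean(dff.values)
    if x.size / fs < 1.0 / signal_band[0]:
        raise ValueError("trace too short to resolve the signal band")
    if not np.any(x):
        dff.qc.update(snr=np.nan, kept=False, reasons=["zero-trace"])
        return np.nan, False
    freqs, power = signal.periodogram(x, fs=fs)
    sig = power[(freqs > signal_band[0]) & (freqs < signal_band[1])]
    noi = power[(freqs > noise_band[0]) & (freqs < noise_band[1])]
    noise_mean = float(np.mean(noi))
    if noise_mean == 0:
        dff.qc.update(snr=np.nan, kept=False, reasons=["zero-noise-band"])
        return np.nan, False
    snr = float(np.mean(sig)) / noise_mean
    kept = snr >= threshold
    dff.qc.update(snr=snr, kept=kept, reasons=[] if kept else ["snr"])
    return snr, kept


def lowpass(values: np.ndarray, frame_rate: float, cutoff: float = DEFAULTS["lowpass_cutoff_hz"]) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass (unit passband gain)."""
    sos = signal.butter(4, cutoff, btype="low", fs=frame_rate, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(values, dtype=float))


def lowpass_and_pool(
    dffs: list[DffTrace], cutoff: float = DEFAULTS["lowpass_cutoff_hz"]
) -> DffTrace:
    """Low-pass each kept axon ΔF/F at ``cutoff`` then average across ROIs.

    The pooled trace stands in for the field of view: axon segments within
    one FoV are treated as samples of a single underlying signal.
    """
    if not dffs:
        raise ValueError("no ROIs to pool")
    rates = {d.frame_rate for d in dffs}
    if len(rates) != 1:
        raise ValueError("ROIs in one FoV must share a frame rate")
    fr = rates.pop()
    filtered = np.stack([lowpass(d.values, fr, cutoff) for d in dffs])
    return DffTrace(filtered.mean(axis=0), fr, qc={"n_pooled": len(dffs)})


def qc_table(
    label_image: np.ndarray,
    dffs: dict[int, DffTrace],
    ci_max: float = DEFAULTS["circularity_max"],
    area_min: float = DEFAULTS["area_min_px"],
    snr_threshold: float = DEFAULTS["snr_threshold"],
) -> pd.DataFrame:
    """Full QC table: morphology plus SNR per label.

    ``dffs`` maps label -> DffTrace; labels failing morphology are not
    required to have a trace.
    """
    table = morphology_filter(roi_geometries(label_image), ci_max, area_min)
    snrs, kept_all, reasons_all = [], [], []
    for _, row in table.iterrows():
        reasons = row["reasons"].split(";") if row["reasons"] else []
        snr = np.nan
        if row["kept"] and row["label"] in dffs:
            snr, keep = activity_snr(dffs[row["label"]], threshold=snr_threshold)
            if not keep:
                reasons.append("snr")
        elif row["kept"]:
            reasons.append("no-trace")
        snrs.append(snr)
        kept_all.append(not reasons)
        reasons_all.append(";".join(reasons))
    table["snr"] = snrs
    table["kept"] = kept_all
    table["reasons"] = reasons_all
    return table
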