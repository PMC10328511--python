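"""Default analysis and simulation parameters.

Every threshold, window and rate used anywhere in the pipeline lives in
DEFAULTS so a YAML run config can override any one of them.  Units are
seconds, Hz, cm/s, pixels, or dimensionless as noted.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import yaml

DEFAULTS: dict = {
    # --- virtual reality / stimulus scheduling ---
    "coupling_gain": 1.0,                # flow units per cm/s locomotion
    "mismatch_interval_mean_s": 12.0,
    "mismatch_interval_sd_s": 2.0,
    "mismatch_duration_s": 1.0,
    "flow_stim_interval_stim_mean_s": 9.0,   # stimulation-response protocol
    "flow_stim_interval_stim_sd_s": 3.0,
    "flow_stim_interval_plast_mean_s": 7.0,  # plasticity protocol
    "flow_stim_interval_plast_sd_s": 1.0,
    "flow_stim_duration_s": 1.0,
    "flow_stim_speed_cmps": 24.0,        # locomotion-equivalent
    "interval_floor_s": 2.0,             # truncation floor of the gap normal
    # --- optogenetics ---
    "opto_pulse_width_s": 0.015,
    "opto_pulse_rate_hz": 20.0,
    "opto_train_duration_s": 1.0,
    "opto_train_interval_mean_s": 7.0,
    "opto_train_interval_sd_s": 1.0,
    "opto_loco_gate_cmps": 4.0,
    # --- frame rates ---
    "frame_rate_lc_hz": 60.0,            # single-plane axon imaging
    "frame_rate_v1_hz": 15.0,            # four-plane somatic imaging
    # --- dF/F and ROI quality control ---
    "dff_percentile": 8.0,
    "dff_window_frames": 1000,
    "circularity_max": 0.14,
    "area_min_px": 150,
    "snr_signal_band_hz": (0.05, 1.0),
    "snr_noise_band_hz": (3.0, 8.0),
    "snr_threshold": 10.0,
    "lowpass_cutoff_hz": 10.0,
    # --- event detection / trial classification (cm/s) ---
    "onset_cross_cmps": 0.4,
    "onset_pre_window_s": 2.0,
    "onset_post_window_s": 1.0,
    "onset_post_mean_cmps": 2.0,
    "lc_loco_threshold_cmps": 1.0,
    "lc_fast_threshold_cmps": 10.0,
    "v1_loco_threshold_cmps": 4.0,
    "v1_stat_threshold_cmps": 1.0,
    "flow_context_window_s": 2.0,
    "flow_context_threshold_cmps": 1.0,
    # --- sham triggers and trial validity ---
    "n_sham_lc": 120,
    "n_sham_v1": 1000,
    "min_valid_trials": 3,
    # --- session inclusion ---
    "inclusion_speed_cmps": 4.0,
    "inclusion_min_fraction": 0.15,
    # --- speed bins for LMI (cm/s, left-open right-closed) ---
    "speed_bins_cmps": ((1.0, 5.0), (5.0, 10.0), (10.0, float("inf"))),
    # --- cell typing ---
    "class_percentiles": (33.0, 66.0),
    # --- axon density ---
    "axon_density_threshold_um_per_um2": 0.002,
    # --- statistics ---
    "n_boot": 10000,
    # --- response windows, seconds relative to trigger ---
    "windows": {
        ("mismatch", "LC"): {"baseline": (-1.0, 0.0), "response": (0.66, 1.66)},
        ("playback_halt", "LC"): {"baseline": (-1.0, 0.0), "response": (0.66, 1.66)},
        ("flow_onset_open_loop", "LC"): {"baseline": (-1.0, 0.0), "response": (1.06, 2.06)},
        ("locomotion_onset", "LC"): {"baseline": (-2.0, -1.5), "response": (0.0, 3.0)},
        ("stimulus", "V1"): {"baseline": (-1.0, 0.0), "response": (0.33, 2.33)},
        ("flow_onset_replay", "V1"): {"baseline": (-1.0, 0.0), "response": (0.73, 2.73)},
        ("locomotion_onset", "V1"): {"baseline": (-2.0, -1.0), "response": (0.66, 4.0)},
    },
    "delta_error_shift_s": 0.66,         # |Error| window precedes the dF/F window by this
}


@dataclass
class RunConfig:
    """A DEFAULTS copy plus overrides, loadable from YAML."""

    params: dict = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    def __getitem__(self, key):
        return self.params[key]

    def override(self, **kwargs) -> "RunConfig":
        unknown = set(kwargs) - set(self.params)
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        out = RunConfig(copy.deepcopy(self.params))
        out.params.update(kwargs)
        return out

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        cfg = cls()
        # windows keys round-trip as "kind|scheme" strings in YAML
        if "windows" in loaded:
            loaded["windows"] = {
                tuple(k.split("|")): v for k, v in loaded["windows"].items()
            }
        return cfg.override(**loaded)

    def to_yaml(self, path) -> None:
        dumpable = copy.deepcopy(self.params)
        dumpable["windows"] = {
            "|".join(k): {kk: list(vv) for kk, vv in v.items()}
            for k, v in dumpable["windows"].items()
        }
        dumpable["speed_bins_cmps"] = [list(b) for b in dumpable["speed_bins_cmps"]]
        dumpable["snr_signal_band_hz"] = list(dumpable["snr_signal_band_hz"])
        dumpable["snr_noise_band_hz"] = list(dumpable["snr_noise_band_hz"])
        dumpable["class_percentiles"] = list(dumpable["class_percentiles"])
        with open(path, "w") as fh:
            yaml.safe_dump(dumpable, fh, sort_keys=True)
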