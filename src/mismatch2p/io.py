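"""Session file I/O: HDF5 sessions, TIFF label images, CSV tables.

HDF5 layout::

    /behavior/{time_s, locomotion_cmps, visualflow_cmps, condition_code}
    /triggers/<kind>/times_s
    /fluorescence/{raw_f, frame_rate_hz}
    /rois/label_image            (optional)
    /pupil/{time_s, diameter_au, blink_mask}   (optional)
    /opto/{laser_on, train_times_s}            (optional)
    /meta  attrs: mouse_id, site_id, dataset_scheme, config_json, seed

All datasets are written with HDF5 object timestamps disabled so that
identical sessions serialize to bit-identical files.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import tifffile

from .session import RoiSet, Session, SessionTimeline

REQUIRED_GROUPS = ("/behavior", "/fluorescence", "/meta")


class SchemaError(ValueError):
    """A session file is missing part of the required layout."""


def _write(group, name, data):
    group.create_dataset(name, data=data, track_times=False)


def write_session(session: Session, path) -> Path:
    """Serialize a Session; write∘read is bit-exact for arrays and metadata."""
    path = Path(path)
    tl = session.timeline
    with h5py.File(path, "w", track_order=True) as f:
        beh = f.create_group("behavior")
        _write(beh, "time_s", tl.time)
        _write(beh, "locomotion_cmps", tl.locomotion)
        _write(beh, "visualflow_cmps", tl.visual_flow)
        _write(beh, "condition_code", tl.condition.astype(np.int8))
        trg = f.create_group("triggers")
        for kind, times in sorted(tl.triggers.items()):
            _write(trg.create_group(kind), "times_s", np.asarray(times, dtype=float))
        flu = f.create_group("fluorescence")
        _write(flu, "raw_f", session.rois.raw_f)
        _write(flu, "frame_rate_hz", float(session.rois.frame_rate))
        if session.rois.label_image is not None:
            _write(f.create_group("rois"), "label_image", session.rois.label_image)
        if session.pupil_diameter is not None:
            pup = f.create_group("pupil")
            _write(pup, "time_s", np.arange(len(session.pupil_diameter)) / tl.frame_rate)
            _write(pup, "diameter_au", np.asarray(session.pupil_diameter, dtype=float))
            if session.blink_mask is not None:
                _write(pup, "blink_mask", np.asarray(session.blink_mask, dtype=np.uint8))
        if session.laser_on is not None:
            opt = f.create_group("opto")
            _write(opt, "laser_on", np.asarray(session.laser_on, dtype=np.uint8))
            _write(opt, "train_times_s",
                   np.asarray(session.opto_train_times
                              if session.opto_train_times is not None else [], dtype=float))
        meta = f.create_group("meta")
        meta.attrs["mouse_id"] = session.mouse_id
        meta.attrs["site_id"] = session.site_id
        meta.attrs["dataset_scheme"] = session.scheme
        meta.attrs["config_json"] = session.config_json
        meta.attrs["seed"] = int(session.seed)
    return path


def read_session(path) -> Session:
    """Load a Session, validating the required layout first."""
    with h5py.File(path, "r") as f:
        missing = [g for g in REQUIRED_GROUPS if g.lstrip("/") not in f]
        if missing:
            raise SchemaError(f"session file missing groups: {missing}")
        beh = f["behavior"]
        flu = f["fluorescence"]
        frame_rate = float(flu["frame_rate_hz"][()])
        triggers = {}
        if "triggers" in f:
            for kind in f["triggers"]:
                triggers[kind] = f["triggers"][kind]["times_s"][()]
        timeline = SessionTimeline(
            time=beh["time_s"][()],
            locomotion=beh["locomotion_cmps"][()],
            visual_flow=beh["visualflow_cmps"][()],
            condition=beh["condition_code"][()],
            triggers=triggers,
            frame_rate=frame_rate,
        )
        rois = RoiSet(
            flu["raw_f"][()],
            frame_rate=frame_rate,
            label_image=f["rois"]["label_image"][()] if "rois" in f else None,
        )
        pupil = blink = laser = train_times = None
        if "pupil" in f:
            pupil = f["pupil"]["diameter_au"][()]
            if "blink_mask" in f["pupil"]:
                blink = f["pupil"]["blink_mask"][()].astype(bool)
        if "opto" in f:
            laser = f["opto"]["laser_on"][()]
            train_times = f["opto"]["train_times_s"][()]
        meta = f["meta"].attrs
        return Session(
            timeline=timeline,
            rois=rois,
            pupil_diameter=pupil,
            blink_mask=blink,
            laser_on=laser,
            opto_train_times=train_times,
            mouse_id=str(meta["mouse_id"]),
            site_id=str(meta["site_id"]),
            scheme=str(meta["dataset_scheme"]),
            seed=int(meta["seed"]),
            config_json=str(meta["config_json"]),
        )


def write_label_image(label_image: np.ndarray, path) -> Path:
    """16-bit TIFF label image (lossless round trip)."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(label_image, dtype=np.uint16))
    return path


def read_label_image(path) -> np.ndarray:
    return tifffile.imread(path)
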