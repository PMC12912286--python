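"""File interfaces: SNIRF (HDF5) export/import, tidy CSV, YAML run configs."""

from __future__ import annotations

import dataclasses
import json

import h5py
import numpy as np
import pandas as pd
import yaml

from .glm import CONDITIONS
from .montage import Montage, build_standard_montage
from .simulate import EventSchedule, NoiseSpec, RawSession, SessionSpec


def _write_str(group: h5py.Group, name: str, value: str) -> None:
    group.create_dataset(name, data=np.bytes_(value))


def save_snirf(raw: RawSession, path) -> None:
    """Write a session as SNIRF v1.0 (continuous-wave intensity + stim groups).

    Probe positions are the nominal 2-D layout coordinates; measurement lists
    index sources/detectors in montage order, with each short channel's
    detector appended after the long-channel detectors.
    """
    m = raw.montage
    sources = list(m.sources)
    detectors = sorted({ch.detector_label for ch in m.channels})
    sc_det_offset = len(detectors)
    sc_detectors = [f"{sc.source_label}-sc" for sc in m.short_channels]

    with h5py.File(path, "w") as f:
        _write_str(f, "formatVersion", "1.0")
        nirs = f.create_group("/nirs")
        meta = nirs.create_group("metaDataTags")
        _write_str(meta, "SubjectID", str(raw.subject))
        _write_str(meta, "MeasurementDate", "unknown")
        _write_str(meta, "MeasurementTime", "unknown")
        _write_str(meta, "LengthUnit", "mm")
        _write_str(meta, "TimeUnit", "s")
        _write_str(meta, "FrequencyUnit", "Hz")

        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(raw.wavelengths_nm, dtype=float))
        layout = m.layout_2d
        src_pos = np.array([layout.get(s, (0.0, 0.0)) for s in sources], dtype=float)
        det_pos = np.array(
            [layout.get(d, (0.0, 0.0)) for d in detectors]
            + [layout.get(sc.source_label, (0.0, 0.0)) for sc in m.short_channels],
            dtype=float,
        )
        probe.create_dataset("sourcePos2D", data=src_pos)
        probe.create_dataset("detectorPos2D", data=det_pos)
        probe.create_dataset(
            "sourceLabels", data=np.array([np.bytes_(s) for s in sources])
        )
        probe.create_dataset(
            "detectorLabels",
            data=np.array([np.bytes_(d) for d in detectors + sc_detectors]),
        )

        data = nirs.create_group("data1")
        n = raw.time.size
        cols, k = [], 0
        for i, name in enumerate(raw.channel_names):
            kind, idx = name[0], int(name[1:])
            if kind == "L":
                ch = m.channel(idx)
                si = sources.index(ch.source_label) + 1
                di = detectors.index(ch.detector_label) + 1
            else:
                sc = m.short_channel(idx)
                si = sources.index(sc.source_label) + 1
                di = sc_det_offset + idx
            for wl in (1, 2):
                k += 1
                ml = data.create_group(f"measurementList{k}")
                ml.create_dataset("sourceIndex", data=si)
                ml.create_dataset("detectorIndex", data=di)
                ml.create_dataset("wavelengthIndex", data=wl)
                ml.create_dataset("dataType", data=1)  # CW amplitude
                ml.create_dataset("dataTypeIndex", data=1)
                cols.append(raw.intensity[i, wl - 1])
        data.create_dataset("dataTimeSeries", data=np.column_stack(cols))
        data.create_dataset("time", data=raw.time)

        for j, cond in enumerate(CONDITIONS, start=1):
            stim = nirs.create_group(f"stim{j}")
            _write_str(stim, "name", cond)
            mask = [c == cond for c in raw.schedule.conditions]
            onsets = np.asarray(raw.schedule.onsets)[mask]
            durs = np.asarray(raw.schedule.durations)[mask]
            stim.create_dataset(
                "data", data=np.column_stack([onsets, durs, np.ones_like(onsets)])
            )


def load_snirf(path, montage: Montage | None = None) -> RawSession:
    """Read a session written by :func:`save_snirf` (or a compatible file)."""
    montage = montage or build_standard_montage()
    with h5py.File(path, "r") as f:
        nirs = f["nirs"]
        data = nirs["data1"]
        time = np.asarray(data["time"])
        ts = np.asarray(data["dataTimeSeries"])
        fs = 1.0 / np.median(np.diff(time))
        sources = [s.decode() for s in nirs["probe"]["sourceLabels"]]
        detectors = [d.decode() for d in nirs["probe"]["detectorLabels"]]
        n_meas = ts.shape[1]
        per_channel: dict[str, dict[int, np.ndarray]] = {}
        long_dets = {ch.detector_label for ch in montage.channels}
        for k in range(1, n_meas + 1):
            ml = data[f"measurementList{k}"]
            si = int(np.asarray(ml["sourceIndex"]))
            di = int(np.asarray(ml["detectorIndex"]))
            wl = int(np.asarray(ml["wavelengthIndex"]))
            src, det = sources[si - 1], detectors[di - 1]
            if det in long_dets:
                match = [
                    ch for ch in montage.channels
                    if ch.source_label == src and ch.detector_label == det
                ]
                name = f"L{match[0].id}"
            else:
                name = f"S{montage.sc_by_source(src).id}"
            per_channel.setdefault(name, {})[wl] = ts[:, k - 1]
        names = [f"L{ch.id}" for ch in montage.channels] + [
            f"S{sc.id}" for sc in montage.short_channels
        ]
        intensity = np.stack(
            [np.stack([per_channel[nm][1], per_channel[nm][2]]) for nm in names]
        )
        onsets, durations, conds = [], [], []
        for j, cond in enumerate(CONDITIONS, start=1):
            key = f"stim{j}"
            if key not in nirs:
                continue
            arr = np.atleast_2d(np.asarray(nirs[key]["data"]))
            for row in arr:
                onsets.append(row[0])
                durations.append(row[1])
                conds.append(cond)
        order = np.argsort(onsets)
        schedule = EventSchedule(
            np.asarray(onsets)[order], np.asarray(durations)[order],
            [conds[i] for i in order],
        )
        subject = 1
        try:
            subject = int(np.asarray(nirs["metaDataTags"]["SubjectID"]).item().decode())
        except Exception:
            pass
    return RawSession(time, intensity, names, float(fs), montage, schedule,
                      montage.wavelengths_nm, subject)


def session_to_csv(raw: RawSession, path) -> None:
    """Long-format CSV: time, channel, wavelength_nm, intensity."""
    n = raw.time.size
    frames = []
    for i, name in enumerate(raw.channel_names):
        for j, wl in enumerate(raw.wavelengths_nm):
            frames.append(pd.DataFrame({
                "time": raw.time, "channel": name,
                "wavelength_nm": wl, "intensity": raw.intensity[i, j],
            }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def truth_to_csv(truth_frame: pd.DataFrame, path) -> None:
    truth_frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_SPEC_FIELDS = {f.name for f in dataclasses.fields(SessionSpec)}
_NOISE_FIELDS = {f.name for f in dataclasses.fields(NoiseSpec)}
_TRUTH_KEYS = {"hbo_amp", "hbr_ratio", "between_subject_sd"}


def load_run_config(path) -> dict:
    """Parse and validate a YAML run config.

    Recognized sections: ``session`` (SessionSpec fields), ``noise``
    (NoiseSpec fields), ``truth`` (hbo_amp, hbr_ratio, between_subject_sd),
    plus top-level ``pipelines``, ``seed``, ``out``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    for section, allowed in (("session", _SPEC_FIELDS), ("noise", _NOISE_FIELDS), ("truth", _TRUTH_KEYS)):
        extra = set(cfg.get(section, {}) or {}) - allowed
        if extra:
            raise ValueError(f"unknown keys in config section {section!r}: {sorted(extra)}")
    return cfg


def config_objects(cfg: dict):
    from .simulate import default_ground_truth

    session_kwargs = dict(cfg.get("session", {}) or {})
    if "isi_range" in session_kwargs:
        session_kwargs["isi_range"] = tuple(session_kwargs["isi_range"])
    spec = SessionSpec(**session_kwargs)
    noise = NoiseSpec(**(cfg.get("noise", {}) or {}))
    truth = default_ground_truth(**(cfg.get("truth", {}) or {}))
    return spec, noise, truth


def write_manifest(path, **fields) -> None:
    with open(path, "w") as fh:
        json.dump(fields, fh, indent=2, sort_keys=True, default=str)
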