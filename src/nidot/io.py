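"""File formats: SNIRF-style HDF5, CSV matrices, event files, JSON sidecars."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import ChannelTimeseries, ProbeLayout, Trial, TrialSchedule


def write_snirf(path, ts: ChannelTimeseries, probe: ProbeLayout | None = None) -> None:
    """Write channel data as a minimal SNIRF-shaped HDF5 container.

    Layout: /formatVersion, /nirs/data1/{dataTimeSeries, time,
    measurementList1..N}, /nirs/probe/{wavelengths, sourcePos3D,
    detectorPos3D}. dataTimeSeries is time x channels per the convention.
    """
    wavelengths = sorted(ts.channels["wavelength_nm"].unique()) if "wavelength_nm" in ts.channels else []
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        d = f.create_group("nirs/data1")
        d.create_dataset("dataTimeSeries", data=ts.data.T)
        d.create_dataset("time", data=ts.times)
        for i, row in enumerate(ts.channels.itertuples(index=False), start=1):
            ml = d.create_group(f"measurementList{i}")
            ml.create_dataset("sourceIndex", data=int(row.source) + 1)
            ml.create_dataset("detectorIndex", data=int(row.detector) + 1)
            if wavelengths:
                ml.create_dataset("wavelengthIndex", data=wavelengths.index(row.wavelength_nm) + 1)
            ml.create_dataset("dataType", data=1)
        p = f.create_group("nirs/probe")
        if wavelengths:
            p.create_dataset("wavelengths", data=np.asarray(wavelengths, dtype=float))
        if probe is not None:
            p.create_dataset("sourcePos3D", data=probe.sources)
            p.create_dataset("detectorPos3D", data=probe.detectors)


def read_snirf(path) -> ChannelTimeseries:
    with h5py.File(path, "r") as f:
        d = f["nirs/data1"]
        data = np.asarray(d["dataTimeSeries"]).T
        time = np.asarray(d["time"])
        wavelengths = np.asarray(f["nirs/probe/wavelengths"]) if "nirs/probe/wavelengths" in f else None
        rows = []
        i = 1
        while f"measurementList{i}" in d:
            ml = d[f"measurementList{i}"]
            row = {
                "source": int(np.asarray(ml["sourceIndex"])) - 1,
                "detector": int(np.asarray(ml["detectorIndex"])) - 1,
            }
            if wavelengths is not None and "wavelengthIndex" in ml:
                row["wavelength_nm"] = float(wavelengths[int(np.asarray(ml["wavelengthIndex"])) - 1])
            rows.append(row)
            i += 1
    table = pd.DataFrame(rows)
    if "distance_mm" not in table:
        table["distance_mm"] = np.nan
    rate = 1.0 / float(np.median(np.diff(time))) if len(time) > 1 else 1.0
    return ChannelTimeseries(data=data, rate_hz=rate, channels=table, kind="od", t0_s=float(time[0]))


def write_channels_csv(ts: ChannelTimeseries, data_path, table_path) -> None:
    """Flat CSV matrix (channels x timepoints) plus a channel table CSV."""
    pd.DataFrame(ts.data).to_csv(data_path, index=False, header=False)
    meta = ts.channels.copy()
    meta.attrs = {}
    meta.to_csv(table_path, index=False)


def read_channels_csv(data_path, table_path, rate_hz: float, kind: str = "od", t0_s: float = 0.0) -> ChannelTimeseries:
    data = pd.read_csv(data_path, header=None).to_numpy(dtype=float)
    table = pd.read_csv(table_path)
    return ChannelTimeseries(data=data, rate_hz=rate_hz, channels=table, kind=kind, t0_s=t0_s)


def write_schedule_csv(schedule: TrialSchedule, path) -> None:
    schedule.to_frame().to_csv(path, index=False)


def read_schedule_csv(path, cue_dur_s: float = 0.75, stim_dur_s: float = 1.8) -> TrialSchedule:
    df = pd.read_csv(path)
    trials = tuple(
        Trial(cue_onset_s=float(r.onset_s), stim_onset_s=float(r.stim_onset_s), type=str(r.type))
        for r in df.itertuples(index=False)
    )
    end = trials[-1].stim_onset_s + stim_dur_s + 3.0 if trials else 0.0
    return TrialSchedule(trials=trials, cue_dur_s=cue_dur_s, stim_dur_s=stim_dur_s, session_end_s=end)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, tuple):
        return list(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")


def config_hash(config_dict: dict) -> str:
    return hashlib.sha256(json.dumps(config_dict, sort_keys=True, default=_jsonable).encode()).hexdigest()[:16]
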