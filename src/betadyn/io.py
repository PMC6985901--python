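"""HDF5 session container.

Layout::

    /meg, /emg, /force     data (channels x samples), fs, channel_labels, kind
    /schedule              trial table columns
    /truth                 lead field, coords, burst annotations, config JSON
    /derived/...           written by analysis stages (parcels, tfs, beta, hmm)
"""

from __future__ import annotations

import dataclasses
import hashlib
import json

import h5py
import numpy as np
import pandas as pd

from .synth import (
    BurstConfig,
    LeadField,
    SCHEDULE_COLUMNS,
    SensorRecording,
    Session,
    SessionConfig,
    SourceActivity,
    TaskSchedule,
)

__all__ = ["save_session", "load_session", "session_checksum", "array_checksum"]


def _write_recording(g: h5py.Group, rec: SensorRecording) -> None:
    g.create_dataset("data", data=rec.data, compression="gzip", compression_opts=1)
    g.attrs["fs"] = rec.fs
    g.attrs["kind"] = rec.kind
    g.attrs["channel_labels"] = json.dumps(list(rec.channel_labels))


def _read_recording(g: h5py.Group) -> SensorRecording:
    return SensorRecording(
        data=g["data"][()],
        fs=float(g.attrs["fs"]),
        channel_labels=json.loads(g.attrs["channel_labels"]),
        kind=str(g.attrs["kind"]),
    )


def _config_to_json(config: SessionConfig) -> str:
    d = dataclasses.asdict(config)
    return json.dumps(d, sort_keys=True)


def _config_from_json(s: str) -> SessionConfig:
    d = json.loads(s)
    bd = d.pop("burst")
    for key in ("post_extra", "post_scale"):
        bd[key] = {float(k): v for k, v in bd[key].items()}
    d["force_sd_pct"] = {float(k): v for k, v in d["force_sd_pct"].items()}
    d["conditions"] = tuple(d["conditions"])
    d["emg_contraction_gain"] = tuple(d["emg_contraction_gain"])
    return SessionConfig(burst=BurstConfig(**bd), **d)


def save_session(session: Session, path) -> None:
    with h5py.File(path, "w") as f:
        for name, rec in (("meg", session.meg), ("emg", session.emg),
                          ("force", session.force)):
            _write_recording(f.create_group(name), rec)

        gs = f.create_group("schedule")
        for col in SCHEDULE_COLUMNS:
            gs.create_dataset(col, data=session.schedule.table[col].to_numpy())
        gs.attrs["cue_lead_s"] = session.schedule.cue_lead_s

        gt = f.create_group("truth")
        gt.create_dataset("gain", data=session.leadfield.gain)
        gt.create_dataset("source_coords", data=session.leadfield.source_coords)
        gt.create_dataset("channel_coords", data=session.leadfield.channel_coords)
        gt.attrs["task_source"] = session.task_source
        gt.attrs["seed"] = session.seed
        gt.attrs["config"] = _config_to_json(session.config)
        gt.create_dataset("probe_times", data=session.probe_times)
        gt.attrs["fs_sources"] = session.sources.fs
        gt.attrs["rate_profile"] = json.dumps(session.sources.burst_rate_profile)
        gt.create_dataset("source_timecourses", data=session.sources.timecourses,
                          compression="gzip", compression_opts=1)
        onsets = session.sources.burst_onsets
        flat_on = np.concatenate([np.asarray(o, dtype=np.int64) for o in onsets]) \
            if onsets else np.zeros(0, dtype=np.int64)
        flat_off = np.concatenate(
            [np.asarray(o, dtype=np.int64) for o in session.sources.burst_offsets]
        ) if onsets else np.zeros(0, dtype=np.int64)
        indptr = np.cumsum([0] + [len(o) for o in onsets]).astype(np.int64)
        gt.create_dataset("burst_onsets", data=flat_on)
        gt.create_dataset("burst_offsets", data=flat_off)
        gt.create_dataset("burst_indptr", data=indptr)


def load_session(path) -> Session:
    with h5py.File(path, "r") as f:
        meg = _read_recording(f["meg"])
        emg = _read_recording(f["emg"])
        force = _read_recording(f["force"])
        gs = f["schedule"]
        table = pd.DataFrame({col: gs[col][()] for col in SCHEDULE_COLUMNS})
        schedule = TaskSchedule(table, cue_lead_s=float(gs.attrs["cue_lead_s"]))
        gt = f["truth"]
        leadfield = LeadField(
            gain=gt["gain"][()],
            source_coords=gt["source_coords"][()],
            channel_coords=gt["channel_coords"][()],
        )
        config = _config_from_json(gt.attrs["config"])
        indptr = gt["burst_indptr"][()]
        flat_on = gt["burst_onsets"][()]
        flat_off = gt["burst_offsets"][()]
        onsets = [flat_on[indptr[i]:indptr[i + 1]] for i in range(len(indptr) - 1)]
        offsets = [flat_off[indptr[i]:indptr[i + 1]] for i in range(len(indptr) - 1)]
        sources = SourceActivity(
            timecourses=gt["source_timecourses"][()],
            fs=float(gt.attrs["fs_sources"]),
            burst_onsets=onsets,
            burst_offsets=offsets,
            burst_rate_profile=json.loads(gt.attrs["rate_profile"]),
        )
        return Session(meg=meg, emg=emg, force=force, schedule=schedule,
                       sources=sources, leadfield=leadfield, config=config,
                       seed=int(gt.attrs["seed"]),
                       task_source=int(gt.attrs["task_source"]),
                       probe_times=gt["probe_times"][()])


def array_checksum(*arrays) -> str:
    """SHA-256 over array payload bytes (dtype/shape tagged)."""
    h = hashlib.sha256()
    for a in arrays:
        a = np.ascontiguousarray(a)
        h.update(str(a.dtype).encode())
        h.update(str(a.shape).encode())
        h.update(a.tobytes())
    return h.hexdigest()


def session_checksum(session: Session) -> str:
    """Deterministic checksum of a session's payload (not file bytes)."""
    return array_checksum(
        session.meg.data, session.emg.data, session.force.data,
        session.schedule.table[SCHEDULE_COLUMNS].to_numpy(),
        session.leadfield.gain, session.sources.timecourses,
    )
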