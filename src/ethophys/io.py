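"""CSV/YAML/HDF5 readers and writers for sessions, spikes, events, features.

Tracking dialect: one row per frame, columns ``time_s`` and
``marker{1..7}_{x,y,z}`` in cm; markers 1-4 are the head rigid body, 5-7
the trunk (neck, back, tail root). Spikes: long table (unit_id,
spike_time_s). Events: one onset per row. Feature tables round-trip
through CSV or HDF5.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .kinematics import TrackingSession
from .synth import EventTrain, SpikeData

__all__ = [
    "write_tracking_csv", "read_tracking_csv",
    "write_spikes_csv", "read_spikes_csv",
    "write_events_csv", "read_events_csv",
    "write_features", "read_features",
]


def write_tracking_csv(session, path):
    cols = {"time_s": session.t}
    markers = np.concatenate([session.head, session.trunk], axis=1)
    for m in range(7):
        for j, ax in enumerate("xyz"):
            cols[f"marker{m + 1}_{ax}"] = markers[:, m, j]
    df = pd.DataFrame(cols)
    df.attrs["condition"] = session.condition
    df.to_csv(path, index=False, float_format="%.5f")


def read_tracking_csv(path, fps=None, condition="light1"):
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    markers = np.stack(
        [df[[f"marker{m + 1}_{ax}" for ax in "xyz"]].to_numpy(dtype=float)
         for m in range(7)], axis=1)
    if fps is None:
        dt = np.median(np.diff(t))
        fps = 1.0 / dt if dt > 0 else 120.0
        if abs(fps - round(fps)) < 0.01 * fps:   # snap rounded timestamps
            fps = float(round(fps))
    return TrackingSession(t=t, head=markers[:, :4], trunk=markers[:, 4:],
                           fps=float(fps), condition=condition)


def write_spikes_csv(spikes, spikes_path, metadata_path=None):
    rows = [(u, t) for u, st in enumerate(spikes.spike_times) for t in st]
    pd.DataFrame(rows, columns=["unit_id", "spike_time_s"]).to_csv(
        spikes_path, index=False, float_format="%.6f")
    if metadata_path is not None:
        spikes.metadata.to_csv(metadata_path, index=False)


def read_spikes_csv(spikes_path, metadata_path=None, duration_s=None):
    df = pd.read_csv(spikes_path)
    meta = pd.read_csv(metadata_path) if metadata_path else pd.DataFrame()
    n_units = int(df["unit_id"].max()) + 1 if len(df) else len(meta)
    if len(meta):
        n_units = max(n_units, len(meta))
    trains = [np.sort(df.loc[df.unit_id == u, "spike_time_s"].to_numpy())
              for u in range(n_units)]
    if duration_s is None:
        duration_s = float(df["spike_time_s"].max()) if len(df) else 0.0
    return SpikeData(spike_times=trains, metadata=meta, duration_s=duration_s)


def write_events_csv(events, path):
    pd.DataFrame({"onset_s": events.onsets}).to_csv(path, index=False)


def read_events_csv(path, duration_s=5.0, session_duration_s=None):
    df = pd.read_csv(path)
    onsets = df["onset_s"].to_numpy(dtype=float)
    if session_duration_s is None:
        session_duration_s = float(onsets.max() + duration_s) if onsets.size else 0.0
    return EventTrain(onsets=onsets, duration_s=duration_s,
                      session_duration_s=session_duration_s)


def write_features(features, path):
    """Feature table to CSV (.csv) or HDF5 (anything else)."""
    path = str(path)
    if path.endswith(".csv"):
        features.to_csv(path, index=False)
    else:
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=features.to_numpy(dtype=float),
                             compression="gzip")
            f.attrs["columns"] = list(features.columns)


def read_features(path):
    path = str(path)
    if path.endswith(".csv"):
        return pd.read_csv(path)
    import h5py
    with h5py.File(path, "r") as f:
        cols = list(f.attrs["columns"])
        vals = f["values"][...]
    return pd.DataFrame(vals, columns=cols)
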