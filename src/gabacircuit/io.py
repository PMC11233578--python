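"""File formats: HDF5 for traces and sweeps, CSV for tabular metadata,
YAML for configuration.  All writes are atomic (temp file + rename)."""

from __future__ import annotations

import os
import tempfile
from dataclasses import asdict, fields
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .simulate import PscSim, PscTrialSet, SessionSet, SimConfig

__all__ = [
    "write_session_hdf5",
    "read_session_hdf5",
    "write_events_csv",
    "read_events_csv",
    "write_sweeps_hdf5",
    "read_sweeps_hdf5",
    "write_psc_hdf5",
    "read_psc_hdf5",
    "save_config_yaml",
    "load_config_yaml",
    "atomic_write_text",
]

EVENT_COLUMNS = ["session", "onset_frame", "duration_frames", "withdrawal", "opto"]


def _atomic_path(path):
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    os.close(fd)
    return path, Path(tmp)


def atomic_write_text(path, text: str) -> None:
    path, tmp = _atomic_path(path)
    tmp.write_text(text)
    tmp.replace(path)


def write_session_hdf5(session_set: SessionSet, path) -> None:
    path, tmp = _atomic_path(path)
    with h5py.File(tmp, "w") as h:
        h.attrs["frame_rate"] = session_set.frame_rate
        h.attrs["n_sessions"] = session_set.n_sessions
        h.create_dataset("ml_coordinate_um", data=session_set.ml_coordinate_um)
        for s in range(session_set.n_sessions):
            g = h.create_group(f"session{s}")
            g.create_dataset("f", data=session_set.fluorescence[s])
            g.create_dataset("background", data=session_set.background[s])
        gt = h.create_group("ground_truth")
        gt.create_dataset("neuron_id", data=session_set.ground_truth.neuron_id.to_numpy())
        gt.create_dataset(
            "cls",
            data=np.array([c.encode() for c in session_set.ground_truth.cls]),
        )
        gt.create_dataset("amplitude", data=session_set.ground_truth.amplitude.to_numpy())
    tmp.replace(path)


def read_session_hdf5(path, events: pd.DataFrame | None = None) -> SessionSet:
    with h5py.File(path, "r") as h:
        for key in ("frame_rate", "n_sessions"):
            if key not in h.attrs:
                raise ValueError(f"missing attribute {key!r} in {path}")
        n_sessions = int(h.attrs["n_sessions"])
        fluo, bg = [], []
        for s in range(n_sessions):
            g = f"session{s}"
            if g not in h or "f" not in h[g] or "background" not in h[g]:
                raise ValueError(f"missing dataset /{g}/f or /{g}/background in {path}")
            fluo.append(h[g]["f"][()])
            bg.append(h[g]["background"][()])
        ml = h["ml_coordinate_um"][()]
        gt = pd.DataFrame(
            dict(
                neuron_id=h["ground_truth"]["neuron_id"][()],
                cls=[c.decode() for c in h["ground_truth"]["cls"][()]],
                amplitude=h["ground_truth"]["amplitude"][()],
            )
        )
        frame_rate = float(h.attrs["frame_rate"])
    if events is None:
        events = pd.DataFrame(columns=EVENT_COLUMNS)
    return SessionSet(fluo, bg, events, ml, gt, frame_rate)


def write_events_csv(events: pd.DataFrame, path) -> None:
    path, tmp = _atomic_path(path)
    events[EVENT_COLUMNS].to_csv(tmp, index=False)
    tmp.replace(path)


def read_events_csv(path, n_frames: int | None = None) -> pd.DataFrame:
    events = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise ValueError(f"events CSV missing columns: {sorted(missing)}")
    if n_frames is not None:
        bad = events.index[
            (events.onset_frame < 0)
            | (events.onset_frame + events.duration_frames > n_frames)
        ].tolist()
        if bad:
            raise ValueError(f"events CSV rows with out-of-range onsets: {bad}")
    return events


def write_sweeps_hdf5(sweeps, path) -> None:
    path, tmp = _atomic_path(path)
    with h5py.File(tmp, "w") as h:
        h.attrs["sampling_rate"] = sweeps.sampling_rate
        h.attrs["step_onset"] = sweeps.step_onset
        h.attrs["step_duration"] = sweeps.step_duration
        h.create_dataset("time", data=sweeps.time)
        h.create_dataset("voltage", data=sweeps.voltage)
        h.create_dataset("current_steps", data=sweeps.current_steps)
    tmp.replace(path)


def read_sweeps_hdf5(path):
    from .simulate import PlantedCellParams, SweepSet

    with h5py.File(path, "r") as h:
        for key in ("sampling_rate", "step_onset", "step_duration"):
            if key not in h.attrs:
                raise ValueError(f"missing attribute {key!r} in {path}")
        return SweepSet(
            time=h["time"][()],
            voltage=h["voltage"][()],
            current_steps=h["current_steps"][()],
            sampling_rate=float(h.attrs["sampling_rate"]),
            step_onset=float(h.attrs["step_onset"]),
            step_duration=float(h.attrs["step_duration"]),
            params=PlantedCellParams(),
        )


def write_psc_hdf5(trials: PscTrialSet, path) -> None:
    path, tmp = _atomic_path(path)
    with h5py.File(tmp, "w") as h:
        h.attrs["sampling_rate"] = trials.sampling_rate
        h.attrs["stim_time_s"] = trials.stim_time_s
        h.create_dataset("trials_minus50", data=trials.trials_minus50)
        h.create_dataset("trials_minus92", data=trials.trials_minus92)
        h.create_dataset("ipsc_present", data=trials.ipsc_present.astype(np.int8))
    tmp.replace(path)


def read_psc_hdf5(path) -> PscTrialSet:
    with h5py.File(path, "r") as h:
        return PscTrialSet(
            trials_minus50=h["trials_minus50"][()],
            trials_minus92=h["trials_minus92"][()],
            stim_time_s=float(h.attrs["stim_time_s"]),
            sampling_rate=float(h.attrs["sampling_rate"]),
            ipsc_present=h["ipsc_present"][()].astype(bool),
            config=PscSim(),
        )


def save_config_yaml(config: SimConfig, path) -> None:
    atomic_write_text(path, yaml.safe_dump(asdict(config), sort_keys=True))


def load_config_yaml(path) -> SimConfig:
    raw = yaml.safe_load(Path(path).read_text())
    known = {f.name for f in fields(SimConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "withdrawal_threshold" not in raw:
        raw["withdrawal_threshold"] = None
    return SimConfig(**raw)
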