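"""Spike-recording data model, HDF5/CSV readers and writers, and threshold
spike detection.

A :class:`SpikeTrain` holds one electrode's sorted spike times (seconds,
0-based at recording start, half-open window ``[t_start, t_end)``).  A
:class:`Recording` is a well-level collection of trains sharing the window
``[0, duration)`` plus device/well/condition/timepoint metadata.

Two on-disk dialects are supported:

* HDF5 — group ``/spikes`` with one 1-D float64 dataset per electrode named
  ``e<k>``; root attributes ``duration_s``, ``device_id``, ``well_id``,
  ``condition``, ``timepoint``.
* CSV — header ``electrode,time_s``, one spike per row; metadata (duration
  and labels) in a JSON sidecar ``<path>.meta.json`` or passed explicitly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "SpikeTrain",
    "Recording",
    "DetectionParams",
    "read_recording",
    "write_recording",
    "detect_spikes",
    "filter_active_electrodes",
]


class FormatError(ValueError):
    """Raised when an on-disk file does not conform to the dialect."""


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times of one electrode within ``[t_start, t_end)``."""

    electrode_id: int
    times: np.ndarray
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=np.float64)
        object.__setattr__(self, "times", times)
        if self.electrode_id < 0:
            raise ValueError("electrode_id must be non-negative")
        if not self.t_end > self.t_start:
            raise ValueError("t_end must exceed t_start")
        if times.ndim != 1:
            raise ValueError("times must be 1-D")
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise ValueError(
                    f"electrode {self.electrode_id}: spike times must be "
                    "strictly increasing"
                )
            if times[0] < self.t_start or times[-1] >= self.t_end:
                raise ValueError(
                    f"electrode {self.electrode_id}: spike times outside "
                    f"[{self.t_start}, {self.t_end})"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_spikes


@dataclass(frozen=True)
class Recording:
    """A well-level set of spike trains over a common window ``[0, duration)``."""

    device_id: str
    well_id: str
    condition: str
    timepoint: str
    duration: float
    trains: dict[int, SpikeTrain] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        for eid, tr in self.trains.items():
            if eid != tr.electrode_id:
                raise ValueError(f"train keyed {eid} has electrode_id {tr.electrode_id}")
            if tr.t_start != 0.0 or tr.t_end != self.duration:
                raise ValueError(
                    f"electrode {eid}: train window [{tr.t_start}, {tr.t_end}) "
                    f"does not match recording [0, {self.duration})"
                )

    @property
    def electrode_ids(self) -> list[int]:
        return sorted(self.trains)

    @property
    def n_electrodes(self) -> int:
        return len(self.trains)

    def spike_counts(self) -> dict[int, int]:
        return {eid: self.trains[eid].n_spikes for eid in self.electrode_ids}


@dataclass(frozen=True)
class DetectionParams:
    """Threshold spike-detection parameters.

    ``threshold_multiplier`` scales a robust noise-SD estimate
    (``median(|x|)/0.6745``); crossings closer than ``dead_time`` to the
    previous accepted crossing are discarded.
    """

    threshold_multiplier: float = 6.5
    polarity: Literal["negative", "positive", "both"] = "negative"
    dead_time: float = 1e-3

    def __post_init__(self) -> None:
        if not self.threshold_multiplier > 0:
            raise ValueError("threshold_multiplier must be positive")
        if self.dead_time < 0:
            raise ValueError("dead_time must be non-negative")
        if self.polarity not in ("negative", "positive", "both"):
            raise ValueError(f"unknown polarity {self.polarity!r}")


def _meta_sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def read_recording(
    path: str | Path,
    format: Literal["hdf5", "csv"] | None = None,
    *,
    duration: float | None = None,
    device_id: str = "",
    well_id: str = "",
    condition: str = "",
    timepoint: str = "",
) -> Recording:
    """Read a :class:`Recording` from an HDF5 or CSV file.

    ``format`` defaults from the suffix (``.h5``/``.hdf5`` vs ``.csv``).  For
    CSV, metadata comes from the ``<path>.meta.json`` sidecar when present;
    explicit keyword arguments override, and ``duration`` is required when no
    sidecar exists.
    """
    path = Path(path)
    if format is None:
        format = "hdf5" if path.suffix.lower() in (".h5", ".hdf5") else "csv"
    if format == "hdf5":
        return _read_hdf5(path)
    if format == "csv":
        return _read_csv(path, duration, device_id, well_id, condition, timepoint)
    raise ValueError(f"unknown format {format!r}")


def _read_hdf5(path: Path) -> Recording:
    with h5py.File(path, "r") as f:
        if "spikes" not in f:
            raise FormatError(f"{path}: missing group '/spikes'")
        try:
            duration = float(f.attrs["duration_s"])
        except KeyError:
            raise FormatError(f"{path}: missing root attribute 'duration_s'")
        meta = {
            k: str(f.attrs.get(k, ""))
            for k in ("device_id", "well_id", "condition", "timepoint")
        }
        trains: dict[int, SpikeTrain] = {}
        for name, ds in f["spikes"].items():
            if not name.startswith("e"):
                raise FormatError(f"{path}: unexpected dataset '/spikes/{name}'")
            try:
                eid = int(name[1:])
            except ValueError:
                raise FormatError(f"{path}: bad electrode dataset name '{name}'")
            times = np.asarray(ds[()], dtype=np.float64)
            try:
                trains[eid] = SpikeTrain(eid, times, 0.0, duration)
            except ValueError as e:
                raise FormatError(f"{path}: dataset '/spikes/{name}': {e}")
    return Recording(
        device_id=meta["device_id"],
        well_id=meta["well_id"],
        condition=meta["condition"],
        timepoint=meta["timepoint"],
        duration=duration,
        trains=trains,
    )


def _read_csv(
    path: Path,
    duration: float | None,
    device_id: str,
    well_id: str,
    condition: str,
    timepoint: str,
) -> Recording:
    sidecar = _meta_sidecar(path)
    meta: dict = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    duration = duration if duration is not None else meta.get("duration_s")
    if duration is None:
        raise ValueError(
            f"{path}: duration required (no sidecar {sidecar.name}, no argument)"
        )
    df = pd.read_csv(path, float_precision="round_trip")
    expected = ["electrode", "time_s"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: header must be {','.join(expected)}")
    trains: dict[int, SpikeTrain] = {}
    for eid, grp in df.groupby("electrode", sort=True):
        times = grp["time_s"].to_numpy(dtype=np.float64)
        try:
            trains[int(eid)] = SpikeTrain(int(eid), times, 0.0, float(duration))
        except ValueError as e:
            raise FormatError(f"{path}: electrode {eid}: {e}")
    # zero-spike electrodes have no rows; the sidecar carries the full roster
    for eid in meta.get("electrodes", []):
        trains.setdefault(
            int(eid), SpikeTrain(int(eid), np.empty(0), 0.0, float(duration))
        )
    return Recording(
        device_id=device_id or meta.get("device_id", ""),
        well_id=well_id or meta.get("well_id", ""),
        condition=condition or meta.get("condition", ""),
        timepoint=timepoint or meta.get("timepoint", ""),
        duration=float(duration),
        trains=trains,
    )


def write_recording(
    rec: Recording, path: str | Path, format: Literal["hdf5", "csv"] | None = None
) -> None:
    """Write a recording; ``read_recording`` round-trips it bit-identically."""
    path = Path(path)
    if format is None:
        format = "hdf5" if path.suffix.lower() in (".h5", ".hdf5") else "csv"
    if format == "hdf5":
        with h5py.File(path, "w") as f:
            f.attrs["duration_s"] = rec.duration
            f.attrs["device_id"] = rec.device_id
            f.attrs["well_id"] = rec.well_id
            f.attrs["condition"] = rec.condition
            f.attrs["timepoint"] = rec.timepoint
            g = f.create_group("spikes")
            for eid in rec.electrode_ids:
                g.create_dataset(f"e{eid}", data=rec.trains[eid].times, dtype="f8")
    elif format == "csv":
        rows = [
            (eid, t)
            for eid in rec.electrode_ids
            for t in rec.trains[eid].times
        ]
        df = pd.DataFrame(rows, columns=["electrode", "time_s"])
        # repr-precision floats so the round-trip is exact
        df.to_csv(path, index=False, float_format=None)
        _meta_sidecar(path).write_text(
            json.dumps(
                {
                    "duration_s": rec.duration,
                    "device_id": rec.device_id,
                    "well_id": rec.well_id,
                    "condition": rec.condition,
                    "timepoint": rec.timepoint,
                    "electrodes": rec.electrode_ids,
                },
                indent=2,
            )
        )
    else:
        raise ValueError(f"unknown format {format!r}")


def detect_spikes(
    trace: Sequence[float] | np.ndarray,
    fs: float,
    params: DetectionParams = DetectionParams(),
) -> np.ndarray:
    """Detect spike times (s) as threshold crossings of a voltage trace.

    The threshold is ``threshold_multiplier`` times a robust noise SD,
    ``median(|trace|)/0.6745``, which is insensitive to the spikes
    themselves.  A crossing is the first sample of an excursion beyond the
    threshold (per ``params.polarity``); detections within ``dead_time`` of
    the previous accepted one are collapsed to the first.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if trace.ndim != 1 or trace.size < 2:
        raise ValueError("trace must be 1-D with at least 2 samples")
    if not fs > 0:
        raise ValueError("fs must be positive")
    noise_sd = np.median(np.abs(trace)) / 0.6745
    if noise_sd == 0.0:
        warnings.warn("constant/zero trace: no noise estimate, returning no spikes")
        return np.empty(0, dtype=np.float64)
    thr = params.threshold_multiplier * noise_sd
    if params.polarity == "negative":
        above = trace < -thr
    elif params.polarity == "positive":
        above = trace > thr
    else:
        above = np.abs(trace) > thr
    # onset samples: above-threshold preceded by below-threshold
    onsets = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    if onsets.size == 0:
        return np.empty(0, dtype=np.float64)
    times = onsets / fs
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= params.dead_time:
            kept.append(t)
    return np.asarray(kept, dtype=np.float64)


def filter_active_electrodes(rec: Recording, min_spikes: int = 10) -> Recording:
    """Drop silent electrodes (fewer than ``min_spikes`` spikes).

    Returns a new :class:`Recording` with only trains whose spike count is at
    least ``min_spikes``; metadata is unchanged and the input untouched.
    """
    kept = {
        eid: tr for eid, tr in rec.trains.items() if tr.n_spikes >= min_spikes
    }
    return replace(rec, trains=kept)
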