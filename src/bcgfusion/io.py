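"""On-disk containers.

Two signal dialects:

* HDF5 — one group per subject: ``/<subject_id>/{bcg,ppg,ecg,beat_times}``
  with ``fs`` and ``ptt_s`` group attributes.  Lossless (keeps ground-truth
  beat times).
* Flat CSV — one file per subject with columns ``t, bcg1..bcg4, ppg, ecg``;
  ``fs`` is recovered from the (strictly increasing, uniform) time column.

Windows are stored in HDF5 as ``/windows/{bcg,ppg}``, ``/labels``,
``/subject_ids``, ``/t_start``; predictions as CSV with columns
``subject_id, t_start, hr_true, hr_pred``.
"""

from __future__ import annotations

import pathlib
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .records import SignalRecord, WindowedSample

__all__ = [
    "write_records_hdf5", "read_records_hdf5", "write_record_csv",
    "read_record_csv", "read_signal_container", "write_signal_container",
    "write_window_store", "read_window_store", "write_predictions_csv",
]

_CSV_COLUMNS = ["t", "bcg1", "bcg2", "bcg3", "bcg4", "ppg", "ecg"]


class FormatError(ValueError):
    """A container does not match the documented dialect."""


# -- HDF5 signal container ---------------------------------------------------

def write_records_hdf5(records: Sequence[SignalRecord], path) -> None:
    with h5py.File(path, "w") as fh:
        for rec in records:
            g = fh.create_group(rec.subject_id)
            g.create_dataset("bcg", data=rec.bcg)
            g.create_dataset("ppg", data=rec.ppg)
            g.create_dataset("ecg", data=rec.ecg)
            if rec.beat_times is not None:
                g.create_dataset("beat_times", data=rec.beat_times)
            g.attrs["fs"] = rec.fs
            g.attrs["ptt_s"] = rec.ptt_s


def read_records_hdf5(path) -> list[SignalRecord]:
    records = []
    with h5py.File(path, "r") as fh:
        for sid in sorted(fh.keys()):
            g = fh[sid]
            fs = float(g.attrs.get("fs", np.nan))
            if not np.isfinite(fs) or fs <= 0:
                raise FormatError(f"subject {sid}: missing or invalid fs")
            bcg = np.asarray(g["bcg"])
            if bcg.ndim != 2 or bcg.shape[1] != 4:
                raise FormatError(
                    f"subject {sid}: bcg must be [N, 4], got {bcg.shape}")
            records.append(SignalRecord(
                subject_id=sid, fs=fs, bcg=bcg,
                ppg=np.asarray(g["ppg"]), ecg=np.asarray(g["ecg"]),
                beat_times=(np.asarray(g["beat_times"])
                            if "beat_times" in g else None),
                ptt_s=float(g.attrs.get("ptt_s", 0.0))))
    return records


# -- flat CSV dialect ---------------------------------------------------------

def write_record_csv(record: SignalRecord, path) -> None:
    t = np.arange(record.n_samples) / record.fs
    df = pd.DataFrame(
        np.column_stack([t, record.bcg, record.ppg, record.ecg]),
        columns=_CSV_COLUMNS)
    df.to_csv(path, index=False)


def read_record_csv(path, subject_id: str | None = None) -> SignalRecord:
    path = pathlib.Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing columns {missing}")
    t = df["t"].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError(f"{path.name}: need at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise FormatError(f"{path.name}: time column t is not monotone")
    fs = 1.0 / float(np.median(dt))
    if not np.isfinite(fs):
        raise FormatError(f"{path.name}: cannot derive fs from t")
    return SignalRecord(
        subject_id=subject_id or path.stem, fs=round(fs, 6),
        bcg=df[["bcg1", "bcg2", "bcg3", "bcg4"]].to_numpy(dtype=float),
        ppg=df["ppg"].to_numpy(dtype=float),
        ecg=df["ecg"].to_numpy(dtype=float))


# -- dispatching reader/writer ------------------------------------------------

def read_signal_container(path, fmt: str | None = None) -> list[SignalRecord]:
    """Read one HDF5 file, one CSV file or a directory of CSVs."""
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        if path.is_dir():
            fmt = "csv"
        else:
            fmt = "hdf5" if path.suffix in (".h5", ".hdf5") else "csv"
    if fmt == "hdf5":
        return read_records_hdf5(path)
    if fmt == "csv":
        if path.is_dir():
            return [read_record_csv(p) for p in sorted(path.glob("*.csv"))]
        return [read_record_csv(path)]
    raise ValueError(f"unknown format {fmt!r}")


def write_signal_container(records: Sequence[SignalRecord], path,
                           fmt: str | None = None) -> None:
    path = pathlib.Path(path)
    if fmt is None:
        fmt = "hdf5" if path.suffix in (".h5", ".hdf5") else "csv"
    if fmt == "hdf5":
        write_records_hdf5(records, path)
    elif fmt == "csv":
        path.mkdir(parents=True, exist_ok=True)
        for rec in records:
            write_record_csv(rec, path / f"{rec.subject_id}.csv")
    else:
        raise ValueError(f"unknown format {fmt!r}")


# -- window store --------------------------------------------------------------

def write_window_store(samples: Sequence[WindowedSample], path) -> None:
    if not samples:
        raise ValueError("no windows to write")
    with h5py.File(path, "w") as fh:
        g = fh.create_group("windows")
        g.create_dataset("bcg", data=np.stack([s.bcg for s in samples]))
        g.create_dataset("ppg", data=np.stack([s.ppg for s in samples]))
        fh.create_dataset("labels", data=[s.hr_bpm for s in samples])
        fh.create_dataset(
            "subject_ids",
            data=np.array([s.subject_id for s in samples], dtype="S"))
        fh.create_dataset("t_start", data=[s.t_start for s in samples])


def read_window_store(path) -> list[WindowedSample]:
    with h5py.File(path, "r") as fh:
        bcg = np.asarray(fh["windows/bcg"])
        ppg = np.asarray(fh["windows/ppg"])
        labels = np.asarray(fh["labels"])
        sids = [s.decode() for s in fh["subject_ids"]]
        t_start = np.asarray(fh["t_start"])
    return [WindowedSample(bcg=bcg[i], ppg=ppg[i], hr_bpm=float(labels[i]),
                           subject_id=sids[i], t_start=float(t_start[i]))
            for i in range(len(labels))]


def write_predictions_csv(subject_ids, t_start, hr_true, hr_pred, path) -> None:
    pd.DataFrame({"subject_id": subject_ids, "t_start": t_start,
                  "hr_true": hr_true, "hr_pred": hr_pred}).to_csv(
        path, index=False)
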