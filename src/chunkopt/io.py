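"""Readers and writers for trial tables and result tables.

Trial tables exist in two dialects that round-trip losslessly:

* CSV (long format): columns ``trial_id, day, t, x, y`` with a header
  comment line declaring the schema and units; capture times live in a
  sibling ``<name>.captures.csv`` with columns
  ``trial_id, element_index, capture_time``.
* HDF5: one group per trial with ``t/x/y`` datasets, ``trial_id``/``day``
  attributes and an optional ``capture_times`` dataset; units stored as
  root attributes.

Units are mandatory (cm, seconds) and validated on read.
"""

from __future__ import annotations

import os
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .kinematics import TrialKinematics

__all__ = ["read_trials", "write_trials", "read_ground_truth",
           "write_ground_truth", "write_results"]

_SCHEMA_LINE = "# chunkopt-trials v1 units: t=s x=cm y=cm"
_COLUMNS = ["trial_id", "day", "t", "x", "y"]


def _captures_path(path: Path) -> Path:
    return path.with_name(path.stem + ".captures.csv")


def write_trials(trials: list[TrialKinematics], path, fmt: str | None = None) -> None:
    """Write trials as CSV or HDF5 (format inferred from the extension)."""
    path = Path(path)
    fmt = fmt or ("hdf5" if path.suffix in {".h5", ".hdf5"} else "csv")
    if fmt == "csv":
        frames = []
        caps = []
        for tr in trials:
            frames.append(pd.DataFrame({
                "trial_id": tr.trial_id, "day": tr.day,
                "t": tr.t, "x": tr.x, "y": tr.y,
            }))
            if tr.capture_times is not None:
                caps.append(pd.DataFrame({
                    "trial_id": tr.trial_id,
                    "element_index": np.arange(1, tr.capture_times.size + 1),
                    "capture_time": tr.capture_times,
                }))
        with open(path, "w") as fh:
            fh.write(_SCHEMA_LINE + "\n")
            pd.concat(frames, ignore_index=True).to_csv(fh, index=False)
        if caps:
            pd.concat(caps, ignore_index=True).to_csv(_captures_path(path), index=False)
    elif fmt == "hdf5":
        with h5py.File(path, "w") as fh:
            fh.attrs["schema"] = "chunkopt-trials v1"
            fh.attrs["units_t"] = "s"
            fh.attrs["units_xy"] = "cm"
            for tr in trials:
                g = fh.create_group(f"trial_{tr.trial_id:06d}")
                g.attrs["trial_id"] = tr.trial_id
                g.attrs["day"] = tr.day
                g.create_dataset("t", data=tr.t)
                g.create_dataset("x", data=tr.x)
                g.create_dataset("y", data=tr.y)
                if tr.capture_times is not None:
                    g.create_dataset("capture_times", data=tr.capture_times)
    else:
        raise ValueError(f"unknown format: {fmt!r}")


def read_trials(path) -> list[TrialKinematics]:
    """Read a trial table (CSV or HDF5); validates schema, units and columns."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in {".h5", ".hdf5"}:
        return _read_hdf5(path)
    return _read_csv(path)


def _read_csv(path: Path) -> list[TrialKinematics]:
    with open(path) as fh:
        first = fh.readline().strip()
    if not first.startswith("#"):
        raise ValueError(f"{path}: missing schema/units header line")
    if "t=s" not in first or "x=cm" not in first:
        raise ValueError(f"{path}: unit mismatch in header {first!r} "
                         "(need t=s, x=cm, y=cm)")
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    caps: dict[int, np.ndarray] = {}
    cpath = _captures_path(path)
    if cpath.exists():
        cdf = pd.read_csv(cpath)
        for tid, sub in cdf.groupby("trial_id"):
            caps[int(tid)] = sub.sort_values("element_index")["capture_time"].to_numpy()
    trials = []
    for tid, sub in df.groupby("trial_id", sort=True):
        sub = sub.reset_index(drop=True)
        try:
            trials.append(TrialKinematics(
                trial_id=int(tid), day=int(sub.day.iloc[0]),
                t=sub.t.to_numpy(), x=sub.x.to_numpy(), y=sub.y.to_numpy(),
                capture_times=caps.get(int(tid)),
            ))
        except ValueError as err:
            row = int(sub.index[0])
            raise ValueError(f"{path}: invalid trial {tid} "
                             f"(rows from {row}): {err}") from err
    return trials


def _read_hdf5(path: Path) -> list[TrialKinematics]:
    trials = []
    with h5py.File(path, "r") as fh:
        if fh.attrs.get("units_t") != "s" or fh.attrs.get("units_xy") != "cm":
            raise ValueError(f"{path}: unit attributes missing or mismatched")
        for name in sorted(fh):
            g = fh[name]
            ct = g["capture_times"][()] if "capture_times" in g else None
            trials.append(TrialKinematics(
                trial_id=int(g.attrs["trial_id"]), day=int(g.attrs["day"]),
                t=g["t"][()], x=g["x"][()], y=g["y"][()], capture_times=ct,
            ))
    return trials


def write_ground_truth(truths, path) -> None:
    pd.DataFrame([{
        "trial_id": gt.trial_id, "day": gt.day,
        "structure": gt.structure.to_bitstring(),
        "chunk_lengths": gt.structure.to_lengths_string(),
    } for gt in truths]).to_csv(path, index=False)


def read_ground_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"structure": str})
    if "structure" not in df.columns:
        raise ValueError(f"{path}: missing 'structure' column")
    return df


def write_results(tables: dict[str, pd.DataFrame], outdir) -> None:
    """Write each table as ``<name>.csv`` under ``outdir``."""
    outdir = Path(outdir)
    os.makedirs(outdir, exist_ok=True)
    for name, df in tables.items():
        if df is not None:
            df.to_csv(outdir / f"{name}.csv", index=False)
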