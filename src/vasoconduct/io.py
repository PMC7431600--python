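"""Tidy-CSV serialization of vessel recordings and derived tables.

The recording dialect is one row per (vessel, position, time) sample:

    vessel_id,group,position_um,time_s,phase,diameter_um

UTF-8, header row, "." decimal separator, missing values empty.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from .synthetic import VesselRecording

RECORDING_COLUMNS = ["vessel_id", "group", "position_um", "time_s", "phase",
                     "diameter_um"]


def recordings_to_frame(recordings: Iterable[VesselRecording]) -> pd.DataFrame:
    rows = []
    for rec in recordings:
        for i, x in enumerate(rec.positions):
            for j, t in enumerate(rec.times):
                d = rec.diameters[i, j]
                rows.append((rec.vessel_id, rec.group_label, x, t,
                             rec.phases[j], d if np.isfinite(d) else np.nan))
    return pd.DataFrame(rows, columns=RECORDING_COLUMNS)


def write_recordings(recordings: Iterable[VesselRecording],
                     path: str | os.PathLike) -> None:
    recordings_to_frame(recordings).to_csv(path, index=False)


class RecordingFormatError(ValueError):
    """Raised when a recordings CSV violates the tidy dialect; carries the
    offending 1-based data row number when one can be identified."""


def _fail(row: int | None, msg: str) -> None:
    where = f" (row {row})" if row is not None else ""
    raise RecordingFormatError(f"malformed recordings CSV{where}: {msg}")


def read_recordings(path: str | os.PathLike) -> list[VesselRecording]:
    """Parse a tidy recordings CSV back into ``VesselRecording`` objects.

    Rows with an empty diameter are treated as absent samples; a position
    is kept only if its full time series is present.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - report as a format error
        raise RecordingFormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        _fail(None, f"missing columns {missing}")

    for col in ("position_um", "time_s", "diameter_um"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            _fail(int(bad.idxmax()) + 1, f"non-numeric value in column {col!r}")
        df[col] = coerced

    neg = df["diameter_um"] <= 0
    if neg.any():
        _fail(int(neg.idxmax()) + 1, "non-positive diameter")

    recordings = []
    for vid, sub in df.groupby("vessel_id", sort=False):
        groups = sub["group"].unique()
        if len(groups) != 1:
            _fail(int(sub.index[0]) + 1,
                  f"vessel {vid!r} assigned to multiple groups {list(groups)}")
        times = np.sort(sub["time_s"].unique())
        phase_by_time = {}
        for _, r in sub.iterrows():
            prev = phase_by_time.setdefault(r["time_s"], r["phase"])
            if prev != r["phase"]:
                _fail(int(r.name) + 1,
                      f"inconsistent phase for vessel {vid!r} at t={r['time_s']}")
        grid = sub.pivot_table(index="position_um", columns="time_s",
                               values="diameter_um", aggfunc="first")
        grid = grid.reindex(columns=times).sort_index()
        complete = grid.notna().all(axis=1)
        grid = grid.loc[complete]
        if grid.shape[0] == 0:
            _fail(int(sub.index[0]) + 1,
                  f"vessel {vid!r} has no position with a complete time series")
        if grid.index[0] != 0.0:
            _fail(int(sub.index[0]) + 1,
                  f"vessel {vid!r} lacks the stimulation-site position 0")
        recordings.append(VesselRecording(
            vessel_id=str(vid), group_label=str(groups[0]),
            positions=grid.index.to_numpy(float), times=times,
            phases=tuple(phase_by_time[t] for t in times),
            diameters=grid.to_numpy(float)))
    if not recordings:
        _fail(None, "no vessels found")
    return recordings
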