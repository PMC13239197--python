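"""Reading, writing and aligning monitor epoch tables, investigator logs and diaries.

Epoch tables are plain CSV exports, one file per monitor, all monitors
started simultaneously so that epoch grids share a common origin.

Dialects (comma-separated, header required, ISO-8601 timestamps):

* thigh monitor:  ``epoch_start, steps, walking_time_s, upright_time_s``
* device monitor: ``epoch_start, var_x, var_y, var_z`` plus optional
  ``vane_steps, vane_walking_time_s, vane_upright_time_s`` (the vendor
  posture classifier's own per-epoch output, used only by the baseline
  comparison and by error component (ii)).

Diary CSV: ``device, don, doff`` with ``device`` one of ``rcw``/``lift``.
Investigator log CSV: ``activity, start, end, observed_steps, condition``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """File does not match the declared dialect (missing/unknown columns, bad labels)."""


class IntegrityError(ValueError):
    """Rows violate table invariants (non-monotone or duplicated epoch starts)."""


class AlignmentError(ValueError):
    """Monitor streams cannot be joined (e.g. mismatched epoch lengths)."""


THIGH_ROLE = "thigh"
DEVICE_ROLES = ("rcw", "lift")
ROLES = (THIGH_ROLE,) + DEVICE_ROLES

THIGH_COLUMNS = ["epoch_start", "steps", "walking_time_s", "upright_time_s"]
DEVICE_COLUMNS = ["epoch_start", "var_x", "var_y", "var_z"]
VANE_COLUMNS = ["vane_steps", "vane_walking_time_s", "vane_upright_time_s"]

#: Activities an investigator logs in the lab. Standing happens between
#: logged activities and is measured by the thigh monitor, not the log.
LOG_ACTIVITIES = ("walk_habitual", "walk_fast", "walk_slow", "sit", "bend", "lie")
WALK_ACTIVITIES = ("walk_habitual", "walk_fast", "walk_slow")
CONDITIONS = ("device_on", "device_off")

REPORT_SCHEMA = "offload-adherence-report/1"


@dataclass
class EpochTable:
    """A single monitor's epoch-level export.

    ``data`` rows follow the role's dialect; derived columns
    (``standing_time_s`` for the thigh, ``v_avg`` for devices) are added on
    construction.
    """

    monitor_id: str
    role: str
    epoch_length: float
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise FormatError(f"unknown monitor role {self.role!r}")
        _check_epoch_index(self.data)


@dataclass
class DiaryInterval:
    """One self-reported don -> doff span for a device."""

    device: str
    don: pd.Timestamp
    doff: pd.Timestamp

    def __post_init__(self) -> None:
        if self.device not in DEVICE_ROLES:
            raise FormatError(f"unknown device label {self.device!r}")
        if not self.doff > self.don:
            raise ValueError(f"diary interval doff {self.doff} <= don {self.don}")


@dataclass
class InvestigatorLogEntry:
    """One observed in-lab activity bout with its wear condition."""

    activity: str
    start: pd.Timestamp
    end: pd.Timestamp
    observed_steps: int
    condition: str

    def __post_init__(self) -> None:
        if self.activity not in LOG_ACTIVITIES:
            raise FormatError(f"unknown activity {self.activity!r}")
        if self.condition not in CONDITIONS:
            raise FormatError(f"unknown condition {self.condition!r}")
        if not self.start < self.end:
            raise ValueError(f"log entry start {self.start} >= end {self.end}")
        if self.observed_steps < 0:
            raise ValueError("observed_steps must be non-negative")
        if self.activity not in WALK_ACTIVITIES and self.observed_steps != 0:
            raise ValueError(
                f"observed_steps must be 0 for non-walking activity {self.activity!r}"
            )


@dataclass
class AlignedStudy:
    """Monitor streams joined onto the thigh monitor's epoch grid.

    ``devices[role]`` has one row per thigh epoch; rows with no device
    counterpart carry ``present == False`` and NaN variance columns and are
    excluded from classification.  ``coverage[role]`` is the fraction of
    thigh epochs with device data.
    """

    epoch_length: float
    thigh: pd.DataFrame
    devices: dict[str, pd.DataFrame] = field(default_factory=dict)
    coverage: dict[str, float] = field(default_factory=dict)


def _check_epoch_index(df: pd.DataFrame) -> None:
    starts = df["epoch_start"]
    if starts.duplicated().any():
        dup = starts[starts.duplicated()].iloc[0]
        raise IntegrityError(f"duplicate epoch_start {dup}")
    if not starts.is_monotonic_increasing:
        raise IntegrityError("epoch_start is not strictly increasing")


def _validate_thigh(df: pd.DataFrame, epoch_length: float) -> pd.DataFrame:
    for col in ("steps", "walking_time_s", "upright_time_s"):
        bad = df.index[df[col] < 0]
        if len(bad):
            raise ValueError(f"negative {col} at row {bad[0]}")
    bad = df.index[df["walking_time_s"] > df["upright_time_s"]]
    if len(bad):
        raise ValueError(f"walking_time_s exceeds upright_time_s at row {bad[0]}")
    bad = df.index[df["upright_time_s"] > epoch_length + 1e-9]
    if len(bad):
        raise ValueError(f"upright_time_s exceeds epoch length at row {bad[0]}")
    df = df.copy()
    df["steps"] = df["steps"].astype(int)
    for col in ("walking_time_s", "upright_time_s"):
        df[col] = df[col].astype(float)
    df["standing_time_s"] = df["upright_time_s"] - df["walking_time_s"]
    return df


def _validate_device(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("var_x", "var_y", "var_z"):
        bad = df.index[df[col] < 0]
        if len(bad):
            raise ValueError(f"negative {col} at row {bad[0]}")
    df = df.copy()
    for col in ("var_x", "var_y", "var_z"):
        df[col] = df[col].astype(float)
    df["v_avg"] = (df["var_x"] + df["var_y"] + df["var_z"]) / 3.0
    if "vane_steps" in df.columns:
        for col in VANE_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"partial VANE columns: missing {col}")
            bad = df.index[df[col] < 0]
            if len(bad):
                raise ValueError(f"negative {col} at row {bad[0]}")
            df[col] = df[col].astype(float)
    return df


def build_epoch_table(
    df: pd.DataFrame, role: str, *, monitor_id: str = "", epoch_length: float = 15.0
) -> EpochTable:
    """Validate a raw dataframe against the role's dialect and derive columns."""
    required = THIGH_COLUMNS if role == THIGH_ROLE else DEVICE_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing columns for role {role!r}: {missing}")
    df = df.copy()
    df["epoch_start"] = pd.to_datetime(df["epoch_start"])
    _check_epoch_index(df)
    if role == THIGH_ROLE:
        df = _validate_thigh(df, epoch_length)
    else:
        df = _validate_device(df)
    return EpochTable(monitor_id or role, role, float(epoch_length), df.reset_index(drop=True))


def read_epoch_table(path: str | Path, role: str, *, epoch_length: float = 15.0) -> EpochTable:
    """Read one monitor's epoch CSV, validating the dialect and invariants."""
    path = Path(path)
    df = pd.read_csv(path)
    return build_epoch_table(df, role, monitor_id=path.stem, epoch_length=epoch_length)


def write_epoch_table(table: EpochTable, path: str | Path) -> None:
    """Write an epoch table back to its CSV dialect (derived columns dropped)."""
    cols = THIGH_COLUMNS if table.role == THIGH_ROLE else DEVICE_COLUMNS
    if table.role != THIGH_ROLE and "vane_steps" in table.data.columns:
        cols = cols + VANE_COLUMNS
    out = table.data[cols].copy()
    out["epoch_start"] = out["epoch_start"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False, float_format="%.10g")


def align_monitors(thigh: EpochTable, devices: Sequence[EpochTable]) -> AlignedStudy:
    """Join device streams onto the thigh epoch grid.

    One output row per thigh epoch; device epochs with no thigh counterpart
    are dropped, thigh epochs with no device counterpart are marked absent
    and counted in the coverage report.
    """
    if thigh.role != THIGH_ROLE:
        raise AlignmentError("first table must be the thigh monitor")
    aligned = AlignedStudy(epoch_length=thigh.epoch_length, thigh=thigh.data.copy())
    grid = thigh.data["epoch_start"]
    for dev in devices:
        if dev.epoch_length != thigh.epoch_length:
            raise AlignmentError(
                f"epoch length mismatch: thigh {thigh.epoch_length} s vs "
                f"{dev.monitor_id} {dev.epoch_length} s"
            )
        joined = pd.merge(grid.to_frame(), dev.data, on="epoch_start", how="left")
        joined["present"] = joined["v_avg"].notna()
        aligned.devices[dev.role] = joined
        aligned.coverage[dev.role] = float(joined["present"].mean()) if len(joined) else 1.0
    return aligned


def read_diary(path: str | Path) -> list[DiaryInterval]:
    """Read a don/doff diary CSV; returns normalized (sorted, merged) intervals.

    An empty file (header only or zero bytes) yields an empty list — the
    device is treated as never donned.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        return []
    df = pd.read_csv(path)
    missing = [c for c in ("device", "don", "doff") if c not in df.columns]
    if missing:
        raise FormatError(f"diary missing columns: {missing}")
    intervals = [
        DiaryInterval(row.device, pd.Timestamp(row.don), pd.Timestamp(row.doff))
        for row in df.itertuples()
    ]
    return normalize_diary(intervals)


def normalize_diary(intervals: Iterable[DiaryInterval]) -> list[DiaryInterval]:
    """Sort per device and merge overlapping or abutting intervals."""
    out: list[DiaryInterval] = []
    by_device: dict[str, list[DiaryInterval]] = {}
    for iv in intervals:
        by_device.setdefault(iv.device, []).append(iv)
    for device in DEVICE_ROLES:
        ivs = sorted(by_device.get(device, []), key=lambda iv: iv.don)
        merged: list[list[pd.Timestamp]] = []
        for iv in ivs:
            if merged and iv.don <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], iv.doff)
            else:
                merged.append([iv.don, iv.doff])
        out.extend(DiaryInterval(device, a, b) for a, b in merged)
    return out


def write_diary(intervals: Iterable[DiaryInterval], path: str | Path) -> None:
    rows = [
        {
            "device": iv.device,
            "don": iv.don.strftime("%Y-%m-%dT%H:%M:%S"),
            "doff": iv.doff.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        for iv in intervals
    ]
    pd.DataFrame(rows, columns=["device", "don", "doff"]).to_csv(path, index=False)


def read_investigator_log(path: str | Path) -> list[InvestigatorLogEntry]:
    df = pd.read_csv(path)
    missing = [
        c for c in ("activity", "start", "end", "observed_steps", "condition") if c not in df.columns
    ]
    if missing:
        raise FormatError(f"investigator log missing columns: {missing}")
    return [
        InvestigatorLogEntry(
            row.activity,
            pd.Timestamp(row.start),
            pd.Timestamp(row.end),
            int(row.observed_steps),
            row.condition,
        )
        for row in df.itertuples()
    ]


def write_investigator_log(entries: Iterable[InvestigatorLogEntry], path: str | Path) -> None:
    rows = [
        {
            "activity": e.activity,
            "start": e.start.strftime("%Y-%m-%dT%H:%M:%S"),
            "end": e.end.strftime("%Y-%m-%dT%H:%M:%S"),
            "observed_steps": e.observed_steps,
            "condition": e.condition,
        }
        for e in entries
    ]
    pd.DataFrame(
        rows, columns=["activity", "start", "end", "observed_steps", "condition"]
    ).to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.Timestamp):
        return obj.isoformat()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_report(summary: Mapping, path: str | Path) -> None:
    """Write a schema-versioned JSON analysis report."""
    doc = {"schema": REPORT_SCHEMA, **_jsonable(summary)}
    Path(path).write_text(json.dumps(doc, indent=2, allow_nan=False) + "\n")


def read_report(path: str | Path) -> dict:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema") != REPORT_SCHEMA:
        raise FormatError(f"unexpected report schema {doc.get('schema')!r}")
    return doc
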