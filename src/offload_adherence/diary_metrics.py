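"""Diary-derived adherence: wear timelines, SC_DA / ST_DA, and outlier QC.

Self-reported don/doff times segment the monitoring horizon into worn and
not-worn intervals per device.  Thigh-measured steps and standing seconds
falling inside worn intervals define the diary-derived adherent step count
(SC_DA) and standing time (ST_DA), the self-report counterpart to the
algorithm-derived SC_AA / ST_AA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import DiaryInterval


@dataclass
class WearTimeline:
    """Sorted, disjoint donned intervals for one device, clipped to the horizon."""

    device: str
    intervals: list[tuple[pd.Timestamp, pd.Timestamp]] = field(default_factory=list)

    @property
    def donned_seconds(self) -> float:
        return float(sum((b - a).total_seconds() for a, b in self.intervals))


@dataclass
class DiaryAdherence:
    sc_da: int
    st_da: float


def build_timeline(
    intervals: Sequence[DiaryInterval],
    horizon: tuple[pd.Timestamp, pd.Timestamp],
    device: str | None = None,
) -> WearTimeline:
    """Merge and clip diary intervals into a wear timeline.

    Intervals partly outside the horizon are clipped (with a warning);
    intervals fully outside are dropped (with a warning).  Abutting or
    overlapping intervals merge.
    """
    h0, h1 = pd.Timestamp(horizon[0]), pd.Timestamp(horizon[1])
    if device is None:
        devices = {iv.device for iv in intervals}
        if len(devices) > 1:
            raise ValueError("mixed devices in diary; pass device= explicitly")
        device = devices.pop() if devices else "rcw"
    clipped: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    for iv in intervals:
        if iv.device != device:
            continue
        a, b = max(iv.don, h0), min(iv.doff, h1)
        if a >= b:
            warnings.warn(f"diary interval {iv.don}–{iv.doff} outside horizon; dropped")
            continue
        if a != iv.don or b != iv.doff:
            warnings.warn(f"diary interval {iv.don}–{iv.doff} clipped to horizon")
        clipped.append((a, b))
    clipped.sort()
    merged: list[list[pd.Timestamp]] = []
    for a, b in clipped:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return WearTimeline(device=device, intervals=[(a, b) for a, b in merged])


def epoch_overlap_fraction(
    epoch_starts: pd.Series, epoch_length: float, timeline: WearTimeline
) -> np.ndarray:
    """Fraction of each epoch covered by donned intervals (timeline disjoint)."""
    starts = pd.to_datetime(epoch_starts).to_numpy().astype("datetime64[ns]").astype(np.int64) / 1e9
    ends = starts + epoch_length
    overlap = np.zeros(len(starts))
    for a, b in timeline.intervals:
        a_s, b_s = a.value / 1e9, b.value / 1e9
        overlap += np.clip(np.minimum(ends, b_s) - np.maximum(starts, a_s), 0.0, None)
    return overlap / epoch_length


def diary_adherent_totals(
    thigh: pd.DataFrame, timeline: WearTimeline, epoch_length: float
) -> DiaryAdherence:
    """SC_DA and ST_DA for one subject x device.

    Steps are indivisible, so an epoch's steps count toward SC_DA iff at
    least half the epoch overlaps a donned interval; standing seconds are
    divisible and are prorated by the exact overlap fraction.
    """
    frac = epoch_overlap_fraction(thigh["epoch_start"], epoch_length, timeline)
    steps = thigh["steps"].to_numpy(dtype=float)
    standing = thigh["standing_time_s"].to_numpy(dtype=float)
    sc_da = steps[frac >= 0.5].sum()
    st_da = float((standing * frac).sum())
    return DiaryAdherence(sc_da=int(sc_da), st_da=st_da)


def qc_exclude_outliers(
    errors: Mapping[str, float],
) -> tuple[list[str], list[str]]:
    """One-pass exclusion of subjects whose error exceeds mean + 2 SD.

    Mean and SD (population SD, ddof=0) are computed over all subjects; the
    cut is one-sided (only unusually *high* error excludes) and applied
    once, without re-iterating on the reduced set.  With fewer than 3
    subjects QC is skipped with a warning and everyone is kept.
    """
    ids = list(errors)
    if len(ids) < 3:
        warnings.warn("fewer than 3 subjects; outlier QC skipped")
        return ids, []
    values = np.array([errors[i] for i in ids], dtype=float)
    cutoff = values.mean() + 2.0 * values.std(ddof=0)
    excluded = [i for i, v in zip(ids, values) if v > cutoff]
    kept = [i for i in ids if i not in excluded]
    return kept, excluded
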