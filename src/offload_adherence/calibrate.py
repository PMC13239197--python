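"""Threshold calibration: subject V_avg extremes, initial estimates, grid search.

Calibration uses the in-lab sessions of a few randomly chosen training
subjects.  Per subject, the extreme V_avg values observed on the device
monitors during thigh-defined standing and thigh-defined walking (device-on
epochs only) bracket the two variance bands; across subjects those extremes
seed an initial threshold pair, which an exhaustive incremental grid search
then refines to maximize classification accuracy while penalizing false
attribution during device-off epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classify import Thresholds


class CalibrationError(RuntimeError):
    """Training data cannot support calibration (e.g. no activity epochs)."""


@dataclass
class SubjectExtremes:
    """Min/max V_avg per activity over one subject's device-on epochs.

    ``standing``/``walking`` are (min, max) tuples, or ``None`` when the
    subject has no device-on epoch of that activity.
    """

    subject_id: str
    standing: tuple[float, float] | None
    walking: tuple[float, float] | None


@dataclass
class GridSpec:
    """Search ranges and resolution for the incremental threshold grid."""

    th_min_range: tuple[float, float]
    th_max_range: tuple[float, float]
    resolution: int = 101

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        if self.resolution < 1:
            raise ValueError("grid resolution must be >= 1")
        return (
            np.linspace(*self.th_min_range, self.resolution),
            np.linspace(*self.th_max_range, self.resolution),
        )


@dataclass
class CalibrationResult:
    thresholds: Thresholds
    objective_value: float
    th_min_grid: np.ndarray
    th_max_grid: np.ndarray
    objective: np.ndarray  # objective[i, j] for (th_min_grid[i], th_max_grid[j])
    training_subject_ids: list[str] = field(default_factory=list)
    degenerate: bool = False


def subject_extremes(
    aligned_device: pd.DataFrame, condition: pd.Series, subject_id: str = ""
) -> SubjectExtremes:
    """Extreme V_avg during thigh-defined standing and walking, device-on.

    Walking epochs are those with thigh steps > 0; standing epochs those
    with thigh standing time > 0 (an epoch can be both when mixed).
    """
    on = (condition == "device_on").to_numpy(dtype=bool)
    present = (
        aligned_device["present"].to_numpy(dtype=bool)
        if "present" in aligned_device.columns
        else np.ones(len(aligned_device), dtype=bool)
    )
    v = aligned_device["v_avg"].to_numpy(dtype=float)
    steps = aligned_device["steps"].to_numpy(dtype=float)
    standing = aligned_device["standing_time_s"].to_numpy(dtype=float)

    def _extreme(mask: np.ndarray) -> tuple[float, float] | None:
        sel = v[mask & on & present]
        if sel.size == 0:
            return None
        return float(sel.min()), float(sel.max())

    return SubjectExtremes(
        subject_id=subject_id,
        standing=_extreme(standing > 0),
        walking=_extreme(steps > 0),
    )


def _pool(extremes: Iterable[SubjectExtremes]):
    standing = [e.standing for e in extremes if e.standing is not None]
    walking = [e.walking for e in extremes if e.walking is not None]
    return standing, walking


def initial_thresholds(extremes: Sequence[SubjectExtremes]) -> Thresholds:
    """Initial threshold estimates from the across-subject extremes.

    th_min starts at the smallest standing-band V_avg seen in any subject;
    th_max starts at the midpoint between the largest standing-band value
    and the smallest walking-band value, or — when the observed bands
    overlap — at the largest standing-band value.
    """
    standing, walking = _pool(extremes)
    if not standing or not walking:
        raise CalibrationError(
            "need at least one training subject with both standing and walking epochs"
        )
    th_min = min(lo for lo, _ in standing)
    standing_hi = max(hi for _, hi in standing)
    walking_lo = min(lo for lo, _ in walking)
    th_max = (standing_hi + walking_lo) / 2.0 if standing_hi < walking_lo else standing_hi
    return Thresholds(th_min=th_min, th_max=th_max)


def default_grid(extremes: Sequence[SubjectExtremes], resolution: int = 101) -> GridSpec:
    """Search ranges spanning the observed band edges.

    th_min sweeps [0, smallest standing V_avg]; th_max sweeps the gap
    between the standing and walking bands, widened by 10% on both sides
    when the observed bands overlap (degenerate gap).
    """
    standing, walking = _pool(extremes)
    if not standing or not walking:
        raise CalibrationError("cannot build a grid without both activity bands")
    standing_lo = min(lo for lo, _ in standing)
    standing_hi = max(hi for _, hi in standing)
    walking_lo = min(lo for lo, _ in walking)
    lo, hi = standing_hi, walking_lo
    if hi <= lo:
        lo, hi = 0.9 * min(lo, hi), 1.1 * max(lo, hi)
    return GridSpec(
        th_min_range=(0.0, standing_lo), th_max_range=(lo, hi), resolution=resolution
    )


def _band_sums(v, weight, th_min_axis, th_max_axis):
    """Sums of ``weight`` over the standing band, separably in the two axes.

    For th_min_i < th_max_j (guaranteed by the grid construction),
    sum(weight | th_min_i < v < th_max_j) = C(j) − D(i) with
    C(j) = sum(weight | v < th_max_j) and D(i) = sum(weight | v <= th_min_i).
    """
    C = (weight[None, :] * (v[None, :] < th_max_axis[:, None])).sum(axis=1)
    D = (weight[None, :] * (v[None, :] <= th_min_axis[:, None])).sum(axis=1)
    return C, D


def optimize_thresholds(
    training: pd.DataFrame,
    grid: GridSpec,
    initial: Thresholds | None = None,
) -> CalibrationResult:
    """Exhaustive grid search for the threshold pair maximizing accuracy.

    ``training`` pools aligned, condition-labeled epochs (columns ``v_avg``,
    ``steps``, ``standing_time_s``, ``condition``; optional ``present``,
    ``subject_id``).  The objective per grid point is

        J = (acc_steps_on + acc_standing_on)/2
            − (false_steps_off + false_standing_off)/2   [percent]

    i.e. balanced device-on accuracy minus balanced device-off false
    attribution.  Ties are broken by lowest combined false attribution,
    then by the tying grid point nearest the centroid of the tying set, so
    a flat optimum returns the plateau midpoint.  ``initial`` is accepted
    for provenance (the grid already spans its neighbourhood) and recorded
    implicitly by the grid ranges.
    """
    th_min_axis, th_max_axis = grid.axes()
    if th_min_axis.size == 0 or th_max_axis.size == 0:
        raise ValueError("empty threshold grid")

    present = (
        training["present"].to_numpy(dtype=bool)
        if "present" in training.columns
        else np.ones(len(training), dtype=bool)
    )
    cond = training["condition"]
    on = (cond == "device_on").to_numpy(dtype=bool) & present
    off = (cond == "device_off").to_numpy(dtype=bool) & present
    v = training["v_avg"].to_numpy(dtype=float)
    steps = training["steps"].to_numpy(dtype=float)
    standing = training["standing_time_s"].to_numpy(dtype=float)

    def _rates(mask):
        tot_steps = steps[mask].sum()
        tot_stand = standing[mask].sum()
        # walking attribution depends on th_max only
        walk_attr = (steps[mask][None, :] * (v[mask][None, :] > th_max_axis[:, None])).sum(axis=1)
        C, D = _band_sums(v[mask], standing[mask], th_min_axis, th_max_axis)
        walk_rate = 100.0 * walk_attr / tot_steps if tot_steps > 0 else np.zeros_like(walk_attr)
        # stand_rate[i, j] = 100 * (C[j] − D[i]) / tot_stand
        if tot_stand > 0:
            stand_rate = 100.0 * (C[None, :] - D[:, None]) / tot_stand
        else:
            stand_rate = np.zeros((th_min_axis.size, th_max_axis.size))
        return walk_rate[None, :], stand_rate

    acc_walk, acc_stand = _rates(on)
    fa_walk, fa_stand = _rates(off)
    J = 0.5 * (acc_walk + acc_stand) - 0.5 * (fa_walk + fa_stand)
    fa_combined = fa_walk + fa_stand

    best = J.max()
    ties = np.argwhere(np.isclose(J, best, rtol=0.0, atol=1e-9))
    degenerate = bool(ties.shape[0] == J.size)
    if ties.shape[0] > 1:
        fa_full = np.broadcast_to(fa_combined, J.shape)
        fa_at_ties = fa_full[ties[:, 0], ties[:, 1]]
        ties = ties[np.isclose(fa_at_ties, fa_at_ties.min(), rtol=0.0, atol=1e-9)]
    pts = np.column_stack([th_min_axis[ties[:, 0]], th_max_axis[ties[:, 1]]])
    centroid = pts.mean(axis=0)
    winner = ties[np.argmin(((pts - centroid) ** 2).sum(axis=1))]
    i, j = int(winner[0]), int(winner[1])

    ids = (
        sorted(training["subject_id"].astype(str).unique())
        if "subject_id" in training.columns
        else []
    )
    return CalibrationResult(
        thresholds=Thresholds(float(th_min_axis[i]), float(th_max_axis[j])),
        objective_value=float(J[i, j]),
        th_min_grid=th_min_axis,
        th_max_grid=th_max_axis,
        objective=np.broadcast_to(J, (th_min_axis.size, th_max_axis.size)).copy(),
        training_subject_ids=ids,
        degenerate=degenerate,
    )


def select_training_subjects(
    subject_ids: Sequence[str], n: int = 5, seed: int | None = None
) -> list[str]:
    """Reproducible uniform sample of training subjects without replacement."""
    ids = sorted(subject_ids)
    if n > len(ids):
        raise ValueError(f"cannot select {n} of {len(ids)} subjects")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(ids), size=n, replace=False)
    return sorted(ids[k] for k in chosen)
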