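"""Epoch-level device-use classification and accuracy/error metrics.

The thigh-worn monitor is the reference for *what* the wearer did in each
15 s epoch (steps, walking time, upright time; standing time = upright −
walking).  A monitor mounted on the removable cast walker (RCW) or on the
contralateral shoe-lift tells us *whether the device moved*: its per-epoch
mean sample-to-sample variation across the three axes,

    V_avg = (X + Y + Z) / 3,

is zero when the device is stationary (not in use), falls in a low band
while the device is worn during standing, and in a high band while worn
during walking.  Given a calibrated threshold pair (th_min, th_max), an
epoch of thigh-defined standing counts as device-adherent standing when
th_min < V_avg < th_max, and an epoch of thigh-defined walking counts as
device-adherent walking when V_avg > th_max, in which case *all* thigh
steps of that epoch are attributed to the device.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import InvestigatorLogEntry


class CapabilityError(RuntimeError):
    """Requested computation needs columns the input table does not carry."""


@dataclass(frozen=True)
class Thresholds:
    """Variance thresholds separating non-use, standing use, and walking use.

    ``th_min < V_avg < th_max`` classifies standing use, ``V_avg > th_max``
    walking use; equality falls into neither band (strict inequalities), and
    ``V_avg <= th_min`` — including the stationarity value 0 — is non-use.
    """

    th_min: float
    th_max: float

    def __post_init__(self) -> None:
        if not 0 <= self.th_min < self.th_max:
            raise ValueError(f"need 0 <= th_min < th_max, got {self}")


@dataclass
class AdherenceSummary:
    """Per subject x device adherent totals and validation metrics.

    ``accuracy_*`` are percentages of device-on thigh activity attributed to
    the device; ``error_*`` are misclassified percentages of total thigh
    activity.  ``None`` marks a metric whose denominator was empty.
    """

    sc_aa: int
    st_aa: float
    total_steps: int
    total_standing: float
    accuracy_steps: float | None = None
    accuracy_standing: float | None = None
    error_steps: float | None = None
    error_standing: float | None = None


def compute_v_avg(var_x, var_y, var_z):
    """Mean sample-to-sample variation across the X, Y and Z axes.

    Accepts scalars or arrays; all inputs must be non-negative.  Zero means
    the device was stationary for the whole epoch.
    """
    x, y, z = (np.asarray(v, dtype=float) for v in (var_x, var_y, var_z))
    if (x < 0).any() or (y < 0).any() or (z < 0).any():
        raise ValueError("axis variations must be non-negative")
    out = (x + y + z) / 3.0
    return float(out) if out.ndim == 0 else out


def derive_standing_time(upright_time, walking_time):
    """Standing time = upright time − walking time (per epoch, seconds)."""
    up = np.asarray(upright_time, dtype=float)
    walk = np.asarray(walking_time, dtype=float)
    if (walk < 0).any() or (up < walk).any():
        raise ValueError("need 0 <= walking_time <= upright_time")
    out = up - walk
    return float(out) if out.ndim == 0 else out


def classify_epochs(aligned: pd.DataFrame, thresholds: Thresholds) -> pd.DataFrame:
    """Classify every aligned epoch of one subject x device.

    ``aligned`` needs columns ``steps``, ``standing_time_s``, ``v_avg`` and
    optionally ``present`` (absent device epochs get no attribution).
    Returns a copy with ``device_used_walking``, ``device_used_standing``,
    ``attributed_steps`` and ``attributed_standing_s`` columns.  Attribution
    is all-or-nothing per epoch: a walking-use epoch contributes all its
    thigh steps, a standing-use epoch all its thigh standing seconds.
    """
    out = aligned.copy()
    v = out["v_avg"].to_numpy(dtype=float)
    present = (
        out["present"].to_numpy(dtype=bool)
        if "present" in out.columns
        else np.isfinite(v)
    )
    v = np.where(present, v, np.nan)
    with np.errstate(invalid="ignore"):
        used_standing = (thresholds.th_min < v) & (v < thresholds.th_max)
        used_walking = v > thresholds.th_max
    used_standing &= present
    used_walking &= present
    steps = out["steps"].to_numpy(dtype=float)
    standing = out["standing_time_s"].to_numpy(dtype=float)
    out["device_used_standing"] = used_standing
    out["device_used_walking"] = used_walking
    out["attributed_steps"] = np.where(used_walking & (steps > 0), steps, 0.0).astype(int)
    out["attributed_standing_s"] = np.where(used_standing & (standing > 0), standing, 0.0)
    return out


def classify_epoch(
    steps: int, standing_time: float, v_avg: float, thresholds: Thresholds
) -> dict:
    """Single-epoch convenience wrapper around :func:`classify_epochs`."""
    df = pd.DataFrame(
        {"steps": [steps], "standing_time_s": [standing_time], "v_avg": [v_avg]}
    )
    row = classify_epochs(df, thresholds).iloc[0]
    return {
        "device_used_walking": bool(row.device_used_walking),
        "device_used_standing": bool(row.device_used_standing),
        "attributed_steps": int(row.attributed_steps),
        "attributed_standing_s": float(row.attributed_standing_s),
    }


def adherent_totals(classified: pd.DataFrame) -> tuple[int, float]:
    """Sum attributed steps and attributed standing seconds (SC_AA, ST_AA)."""
    if len(classified) == 0:
        return 0, 0.0
    return (
        int(classified["attributed_steps"].sum()),
        float(classified["attributed_standing_s"].sum()),
    )


def _pct(num: float, den: float) -> float | None:
    return None if den == 0 else 100.0 * num / den


def accuracy(classified_on: pd.DataFrame) -> tuple[float | None, float | None]:
    """Percent of device-on thigh steps / standing seconds attributed to the device.

    The input must already be restricted to device-on epochs.  Returns
    ``None`` for a component whose thigh-derived denominator is zero.
    """
    sc_aa, st_aa = adherent_totals(classified_on)
    total_steps = float(classified_on["steps"].sum()) if len(classified_on) else 0.0
    total_stand = float(classified_on["standing_time_s"].sum()) if len(classified_on) else 0.0
    return _pct(sc_aa, total_steps), _pct(st_aa, total_stand)


def label_conditions(
    epoch_starts: pd.Series, log: Sequence[InvestigatorLogEntry], epoch_length: float
) -> pd.Series:
    """Assign each epoch its device-on/off condition from the investigator log.

    Each condition's span runs from its first logged activity start to its
    last logged activity end, so unlogged standing between activities
    inherits the surrounding condition.  An epoch is labeled when at least
    half of it lies inside a span; epochs in neither span (e.g. while
    devices were being donned) stay unlabeled (None).
    """
    labels = pd.Series([None] * len(epoch_starts), index=epoch_starts.index, dtype=object)
    half = pd.Timedelta(seconds=epoch_length / 2.0)
    mid = pd.to_datetime(epoch_starts) + half
    for condition in ("device_off", "device_on"):
        entries = [e for e in log if e.condition == condition]
        if not entries:
            continue
        span_start = min(e.start for e in entries)
        span_end = max(e.end for e in entries)
        labels[(mid >= span_start) & (mid <= span_end)] = condition
    return labels


def _vane_standing(classified: pd.DataFrame) -> np.ndarray:
    up = classified["vane_upright_time_s"].to_numpy(dtype=float)
    walk = classified["vane_walking_time_s"].to_numpy(dtype=float)
    return np.clip(up - walk, 0.0, None)


def error_rate(
    classified: pd.DataFrame, condition: pd.Series
) -> tuple[float | None, float | None]:
    """Misclassification error for steps and standing, in percent.

    Sums the activity attributed to the device during (i) device-off epochs
    and (ii) device-on epochs where the thigh showed none of that activity
    but the device-use criterion held — there the device monitor's own
    VANE-reported amount is the only available quantity — and expresses the
    sum relative to total thigh-derived activity over all labeled epochs.
    """
    labeled = condition.notna().to_numpy() if condition.dtype == object else condition.notna()
    labeled = np.asarray(labeled, dtype=bool)
    on = (condition == "device_on").to_numpy(dtype=bool)
    off = (condition == "device_off").to_numpy(dtype=bool)

    steps = classified["steps"].to_numpy(dtype=float)
    standing = classified["standing_time_s"].to_numpy(dtype=float)
    attr_steps = classified["attributed_steps"].to_numpy(dtype=float)
    attr_stand = classified["attributed_standing_s"].to_numpy(dtype=float)
    used_walk = classified["device_used_walking"].to_numpy(dtype=bool)
    used_stand = classified["device_used_standing"].to_numpy(dtype=bool)

    err_steps_num = attr_steps[off].sum()
    err_stand_num = attr_stand[off].sum()

    has_vane = "vane_steps" in classified.columns
    if has_vane:
        vane_steps = classified["vane_steps"].to_numpy(dtype=float)
        vane_stand = _vane_standing(classified)
        phantom_walk = on & (steps == 0) & used_walk
        phantom_stand = on & (standing == 0) & used_stand
        err_steps_num += np.nansum(vane_steps[phantom_walk])
        err_stand_num += np.nansum(vane_stand[phantom_stand])

    return (
        _pct(err_steps_num, steps[labeled].sum()),
        _pct(err_stand_num, standing[labeled].sum()),
    )


def vane_baseline_accuracy(
    aligned: pd.DataFrame, condition: pd.Series
) -> tuple[float | None, float | None]:
    """Accuracy of the vendor VANE output from a device monitor, device-on.

    100 x (sum of VANE-reported steps) / (sum of thigh steps) during the
    device-on condition, and analogously for standing time.  Values above
    100 indicate over-counting.  Requires the optional VANE columns.
    """
    if "vane_steps" not in aligned.columns:
        raise CapabilityError("device table carries no VANE columns")
    on = (condition == "device_on").to_numpy(dtype=bool)
    present = (
        aligned["present"].to_numpy(dtype=bool)
        if "present" in aligned.columns
        else np.ones(len(aligned), dtype=bool)
    )
    sel = on & present
    vane_steps = np.nansum(aligned["vane_steps"].to_numpy(dtype=float)[sel])
    vane_stand = _vane_standing(aligned)[sel].sum()
    return (
        _pct(vane_steps, aligned["steps"].to_numpy(dtype=float)[sel].sum()),
        _pct(vane_stand, aligned["standing_time_s"].to_numpy(dtype=float)[sel].sum()),
    )


def summarize(
    classified: pd.DataFrame, condition: pd.Series
) -> AdherenceSummary:
    """Bundle adherent totals with accuracy (device-on) and error metrics."""
    on = classified[(condition == "device_on").to_numpy(dtype=bool)]
    acc_steps, acc_stand = accuracy(on)
    err_steps, err_stand = error_rate(classified, condition)
    sc_aa, st_aa = adherent_totals(on)
    return AdherenceSummary(
        sc_aa=sc_aa,
        st_aa=st_aa,
        total_steps=int(on["steps"].sum()) if len(on) else 0,
        total_standing=float(on["standing_time_s"].sum()) if len(on) else 0.0,
        accuracy_steps=acc_steps,
        accuracy_standing=acc_stand,
        error_steps=err_steps,
        error_standing=err_stand,
    )
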