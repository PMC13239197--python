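"""End-to-end validation pipelines: calibrate -> classify -> score -> agree.

`run_inlab_study` replays the laboratory validation: simulate (or accept)
per-subject sessions, calibrate thresholds on a few randomly chosen
training subjects, classify everyone, compute per-subject accuracy and
error, apply the mean+2SD outlier exclusion, and measure ICC agreement
between thigh-measured and algorithm-attributed device-on totals.

`run_community_study` replays the 24-h functional check: classify each
subject's free-living day with the calibrated thresholds and compare
algorithm-derived adherence (SC_AA/ST_AA) against diary-derived adherence
(SC_DA/ST_DA) with ICC and Bland-Altman statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import calibrate as _calibrate
from . import classify as _classify
from .agreement import AgreementResult, icc_two_way_random
from .diary_metrics import build_timeline, diary_adherent_totals, qc_exclude_outliers
from .io import DEVICE_ROLES, align_monitors
from .synth import InLabSession, ScenarioConfig, generate_community_day, generate_inlab_session

METRICS = ("steps", "standing")


@dataclass
class InLabStudyResult:
    thresholds: _classify.Thresholds
    calibration: _calibrate.CalibrationResult
    per_subject: pd.DataFrame  # one row per subject x device
    kept_ids: list[str]
    excluded_ids: list[str]
    icc: dict[tuple[str, str], AgreementResult] = field(default_factory=dict)

    def mean_metric(self, column: str, device: str) -> float:
        rows = self.per_subject
        sel = rows[(rows.device == device) & rows.subject.isin(self.kept_ids)]
        return float(sel[column].mean())


@dataclass
class CommunityStudyResult:
    thresholds: _classify.Thresholds
    per_subject: pd.DataFrame  # subject x device with AA and DA totals
    kept_ids: list[str] = field(default_factory=list)
    excluded_ids: list[str] = field(default_factory=list)
    icc: dict[tuple[str, str], AgreementResult] = field(default_factory=dict)


def _classified_session(
    session: InLabSession, thresholds: _classify.Thresholds
) -> dict[str, tuple[pd.DataFrame, pd.Series]]:
    """Aligned + classified device frames with condition labels for one session."""
    aligned = align_monitors(session.thigh, list(session.devices.values()))
    condition = _classify.label_conditions(
        aligned.thigh["epoch_start"], session.log, aligned.epoch_length
    )
    out = {}
    for role in DEVICE_ROLES:
        merged = pd.concat(
            [
                aligned.thigh[["epoch_start", "steps", "standing_time_s"]].reset_index(drop=True),
                aligned.devices[role].drop(columns=["epoch_start"]).reset_index(drop=True),
            ],
            axis=1,
        )
        out[role] = (_classify.classify_epochs(merged, thresholds), condition)
    return out


def _training_frame(
    sessions: dict[str, InLabSession], training_ids: Sequence[str]
) -> tuple[pd.DataFrame, list[_calibrate.SubjectExtremes]]:
    """Pooled RCW+lift condition-labeled epochs and per-subject extremes."""
    frames = []
    extremes = []
    for sid in training_ids:
        session = sessions[sid]
        aligned = align_monitors(session.thigh, list(session.devices.values()))
        condition = _classify.label_conditions(
            aligned.thigh["epoch_start"], session.log, aligned.epoch_length
        )
        for role in DEVICE_ROLES:
            merged = pd.concat(
                [
                    aligned.thigh[["steps", "standing_time_s"]].reset_index(drop=True),
                    aligned.devices[role][["v_avg", "present"]].reset_index(drop=True),
                ],
                axis=1,
            )
            merged["condition"] = condition.reset_index(drop=True)
            merged["subject_id"] = sid
            merged["device"] = role
            frames.append(merged)
            extremes.append(
                _calibrate.subject_extremes(merged, merged["condition"], subject_id=sid)
            )
    return pd.concat(frames, ignore_index=True), extremes


def calibrate_from_sessions(
    sessions: dict[str, InLabSession],
    training_ids: Sequence[str],
    *,
    grid_resolution: int = 101,
    per_device: bool = False,
) -> dict[str, _calibrate.CalibrationResult]:
    """Calibrate thresholds on the training subjects' lab sessions.

    Default is the shared mode: one threshold pair fit on pooled RCW + lift
    epochs and applied to both devices.  ``per_device=True`` fits each
    device separately.
    """
    training, extremes = _training_frame(sessions, training_ids)
    results: dict[str, _calibrate.CalibrationResult] = {}
    if per_device:
        for role in DEVICE_ROLES:
            sub = training[training.device == role]
            ext = [
                _calibrate.subject_extremes(g, g["condition"], subject_id=sid)
                for sid, g in sub.groupby("subject_id")
            ]
            grid = _calibrate.default_grid(ext, resolution=grid_resolution)
            results[role] = _calibrate.optimize_thresholds(
                sub, grid, _calibrate.initial_thresholds(ext)
            )
    else:
        grid = _calibrate.default_grid(extremes, resolution=grid_resolution)
        shared = _calibrate.optimize_thresholds(
            training, grid, _calibrate.initial_thresholds(extremes)
        )
        for role in DEVICE_ROLES:
            results[role] = shared
    return results


def run_inlab_study(
    config: ScenarioConfig,
    *,
    n_training: int = 5,
    grid_resolution: int = 101,
    per_device: bool = False,
    apply_qc: bool = True,
    thresholds: _classify.Thresholds | None = None,
) -> InLabStudyResult:
    """Simulate and score the laboratory validation study."""
    ids = config.subject_ids()
    sessions = {
        sid: generate_inlab_session(config, i) for i, sid in enumerate(ids)
    }

    if thresholds is None:
        training_ids = _calibrate.select_training_subjects(ids, n=n_training, seed=config.seed)
        calib = calibrate_from_sessions(
            sessions, training_ids, grid_resolution=grid_resolution, per_device=per_device
        )
    else:
        calib = {
            role: _calibrate.CalibrationResult(
                thresholds=thresholds,
                objective_value=float("nan"),
                th_min_grid=np.array([thresholds.th_min]),
                th_max_grid=np.array([thresholds.th_max]),
                objective=np.full((1, 1), np.nan),
            )
            for role in DEVICE_ROLES
        }

    rows = []
    on_totals: dict[tuple[str, str], dict[str, list[float]]] = {
        (role, metric): {"thigh": [], "algorithm": []}
        for role in DEVICE_ROLES
        for metric in METRICS
    }
    for sid in ids:
        classified = _classified_session(sessions[sid], calib[DEVICE_ROLES[0]].thresholds)
        for role in DEVICE_ROLES:
            frame, condition = (
                classified[role]
                if not per_device
                else _classified_session(sessions[sid], calib[role].thresholds)[role]
            )
            summary = _classify.summarize(frame, condition)
            vane_steps, vane_stand = _classify.vane_baseline_accuracy(frame, condition)
            rows.append(
                {
                    "subject": sid,
                    "device": role,
                    "sc_aa": summary.sc_aa,
                    "st_aa": summary.st_aa,
                    "total_steps_on": summary.total_steps,
                    "total_standing_on": summary.total_standing,
                    "accuracy_steps": summary.accuracy_steps,
                    "accuracy_standing": summary.accuracy_standing,
                    "error_steps": summary.error_steps,
                    "error_standing": summary.error_standing,
                    "vane_accuracy_steps": vane_steps,
                    "vane_accuracy_standing": vane_stand,
                }
            )
            on_totals[(role, "steps")]["thigh"].append(summary.total_steps)
            on_totals[(role, "steps")]["algorithm"].append(summary.sc_aa)
            on_totals[(role, "standing")]["thigh"].append(summary.total_standing)
            on_totals[(role, "standing")]["algorithm"].append(summary.st_aa)

    per_subject = pd.DataFrame(rows)
    if apply_qc:
        combined = (
            per_subject.groupby("subject")[["error_steps", "error_standing"]]
            .mean()
            .mean(axis=1)
        )
        kept, excluded = qc_exclude_outliers(combined.to_dict())
    else:
        kept, excluded = ids, []

    kept_idx = [ids.index(sid) for sid in kept]
    icc = {}
    for (role, metric), vals in on_totals.items():
        a = np.array(vals["thigh"])[kept_idx]
        b = np.array(vals["algorithm"])[kept_idx]
        icc[(role, metric)] = icc_two_way_random(a, b)

    any_role = DEVICE_ROLES[0]
    return InLabStudyResult(
        thresholds=calib[any_role].thresholds,
        calibration=calib[any_role],
        per_subject=per_subject,
        kept_ids=list(kept),
        excluded_ids=list(excluded),
        icc=icc,
    )


def run_community_study(
    config: ScenarioConfig, thresholds: _classify.Thresholds, *, apply_qc: bool = True
) -> CommunityStudyResult:
    """Simulate and score the 24-h community monitoring check.

    With ``apply_qc`` (default), subjects whose algorithm-vs-diary
    discrepancy |DA − AA| exceeds mean + 2 SD on any metric x device series
    are excluded before agreement is computed — diary entries that disagree
    that much with the monitors are not trustworthy self-reports.
    """
    ids = config.subject_ids()
    rows = []
    for i, sid in enumerate(ids):
        day = generate_community_day(config, i)
        aligned = align_monitors(day.thigh, list(day.devices.values()))
        n = len(aligned.thigh)
        horizon = (
            aligned.thigh["epoch_start"].iloc[0],
            aligned.thigh["epoch_start"].iloc[-1] + pd.Timedelta(seconds=config.epoch_length),
        )
        for role in DEVICE_ROLES:
            merged = pd.concat(
                [
                    aligned.thigh[["epoch_start", "steps", "standing_time_s"]].reset_index(drop=True),
                    aligned.devices[role].drop(columns=["epoch_start"]).reset_index(drop=True),
                ],
                axis=1,
            )
            classified = _classify.classify_epochs(merged, thresholds)
            sc_aa, st_aa = _classify.adherent_totals(classified)
            timeline = build_timeline(
                [iv for iv in day.diary if iv.device == role], horizon, device=role
            )
            da = diary_adherent_totals(aligned.thigh, timeline, config.epoch_length)
            rows.append(
                {
                    "subject": sid,
                    "device": role,
                    "sc_aa": sc_aa,
                    "st_aa": st_aa,
                    "sc_da": da.sc_da,
                    "st_da": da.st_da,
                    "true_adherent_steps": day.truth.true_adherent_steps[role],
                    "true_adherent_standing_s": day.truth.true_adherent_standing_s[role],
                }
            )
    per_subject = pd.DataFrame(rows)

    excluded: set[str] = set()
    if apply_qc:
        for role in DEVICE_ROLES:
            sel = per_subject[per_subject.device == role].set_index("subject")
            for aa_col, da_col in (("sc_aa", "sc_da"), ("st_aa", "st_da")):
                disc = (sel[da_col] - sel[aa_col]).abs()
                _, series_excluded = qc_exclude_outliers(disc.to_dict())
                excluded.update(series_excluded)
    kept = [sid for sid in ids if sid not in excluded]

    icc = {}
    for role in DEVICE_ROLES:
        sel = per_subject[
            (per_subject.device == role) & per_subject.subject.isin(kept)
        ]
        icc[(role, "steps")] = icc_two_way_random(sel["sc_aa"], sel["sc_da"])
        icc[(role, "standing")] = icc_two_way_random(sel["st_aa"], sel["st_da"])
    return CommunityStudyResult(
        thresholds=thresholds,
        per_subject=per_subject,
        kept_ids=kept,
        excluded_ids=sorted(excluded),
        icc=icc,
    )


def run_validation_study(
    config: ScenarioConfig,
    *,
    n_training: int = 5,
    grid_resolution: int = 101,
    per_device: bool = False,
    apply_qc: bool = True,
    thresholds: _classify.Thresholds | None = None,
) -> dict:
    """Full pipeline (lab calibration + 24-h agreement); returns a report dict."""
    inlab = run_inlab_study(
        config,
        n_training=n_training,
        grid_resolution=grid_resolution,
        per_device=per_device,
        apply_qc=apply_qc,
        thresholds=thresholds,
    )
    community = run_community_study(config, inlab.thresholds, apply_qc=apply_qc)
    return {
        "seed": config.seed,
        "n_subjects": config.n_subjects,
        "thresholds": {"th_min": inlab.thresholds.th_min, "th_max": inlab.thresholds.th_max},
        "inlab": summarize_inlab(inlab),
        "community": summarize_community(community),
    }


def summarize_inlab(result: InLabStudyResult) -> dict:
    out = {
        "kept_subjects": result.kept_ids,
        "excluded_subjects": result.excluded_ids,
        "devices": {},
    }
    for role in DEVICE_ROLES:
        icc_steps = result.icc[(role, "steps")]
        icc_stand = result.icc[(role, "standing")]
        out["devices"][role] = {
            "accuracy_steps_pct": result.mean_metric("accuracy_steps", role),
            "accuracy_standing_pct": result.mean_metric("accuracy_standing", role),
            "error_steps_pct": result.mean_metric("error_steps", role),
            "error_standing_pct": result.mean_metric("error_standing", role),
            "vane_accuracy_steps_pct": result.mean_metric("vane_accuracy_steps", role),
            "vane_accuracy_standing_pct": result.mean_metric("vane_accuracy_standing", role),
            "icc_steps": icc_steps.icc,
            "icc_steps_p": icc_steps.p_value,
            "icc_standing": icc_stand.icc,
            "icc_standing_p": icc_stand.p_value,
        }
    return out


def summarize_community(result: CommunityStudyResult) -> dict:
    out = {
        "kept_subjects": result.kept_ids,
        "excluded_subjects": result.excluded_ids,
        "devices": {},
    }
    for role in DEVICE_ROLES:
        sel = result.per_subject[
            (result.per_subject.device == role)
            & result.per_subject.subject.isin(result.kept_ids)
        ]
        dev = {}
        for metric, aa_col, da_col in (
            ("steps", "sc_aa", "sc_da"),
            ("standing", "st_aa", "st_da"),
        ):
            res = result.icc[(role, metric)]
            dev[metric] = {
                "icc": res.icc,
                "p": res.p_value,
                "interpretation": res.interpretation,
                "bias": res.bias,
                "loa_low": res.loa_low,
                "loa_high": res.loa_high,
                "mean_aa": float(sel[aa_col].mean()),
                "mean_da": float(sel[da_col].mean()),
            }
        out["devices"][role] = dev
    return out
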