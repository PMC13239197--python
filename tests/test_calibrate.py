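import numpy as np
import pandas as pd
import pytest

from offload_adherence import (
    GridSpec,
    ScenarioConfig,
    SubjectExtremes,
    Thresholds,
    initial_thresholds,
    optimize_thresholds,
    select_training_subjects,
    subject_extremes,
)
from offload_adherence.calibrate import CalibrationError
from offload_adherence.study import calibrate_from_sessions
from offload_adherence.synth import generate_inlab_session


def _frame(v_by_rows):
    """rows of (v_avg, steps, standing_s, condition)"""
    return pd.DataFrame(
        {
            "v_avg": [r[0] for r in v_by_rows],
            "steps": [r[1] for r in v_by_rows],
            "standing_time_s": [r[2] for r in v_by_rows],
            "condition": [r[3] for r in v_by_rows],
        }
    )


class TestSubjectExtremes:
    def test_standing_min_max(self):
        df = _frame([(0.1, 0, 10.0, "device_on"), (0.3, 0, 10.0, "device_on")])
        ext = subject_extremes(df, df["condition"], "S01")
        assert ext.standing == (0.1, 0.3)
        assert ext.walking is None

    def test_single_walking_epoch(self):
        df = _frame([(2.0, 20, 0.0, "device_on")])
        ext = subject_extremes(df, df["condition"])
        assert ext.walking == (2.0, 2.0)

    def test_device_off_epochs_ignored(self):
        df = _frame([(9.0, 20, 0.0, "device_off"), (2.0, 20, 0.0, "device_on")])
        ext = subject_extremes(df, df["condition"])
        assert ext.walking == (2.0, 2.0)


class TestInitialThresholds:
    def test_midpoint_rule(self):
        ext = [
            SubjectExtremes("a", standing=(0.1, 0.4), walking=(1.5, 3.0)),
            SubjectExtremes("b", standing=(0.2, 0.5), walking=(2.0, 4.0)),
        ]
        th = initial_thresholds(ext)
        assert th.th_min == pytest.approx(0.1)
        assert th.th_max == pytest.approx((0.5 + 1.5) / 2)

    def test_single_subject(self):
        ext = [SubjectExtremes("a", standing=(0.2, 0.6), walking=(1.8, 3.0))]
        th = initial_thresholds(ext)
        assert th.th_min == pytest.approx(0.2)
        assert th.th_max == pytest.approx(1.2)

    def test_overlap_falls_back_to_standing_max(self):
        ext = [SubjectExtremes("a", standing=(0.2, 2.0), walking=(1.5, 3.0))]
        th = initial_thresholds(ext)
        assert th.th_max == pytest.approx(2.0)

    def test_no_activity_raises(self):
        with pytest.raises(CalibrationError):
            initial_thresholds([SubjectExtremes("a", standing=None, walking=None)])


def _brute_force_objective(training, th_min, th_max):
    on = training[training.condition == "device_on"]
    off = training[training.condition == "device_off"]

    def rates(df):
        walk = 100.0 * df.steps[(df.v_avg > th_max)].sum() / max(df.steps.sum(), 1e-12)
        band = (th_min < df.v_avg) & (df.v_avg < th_max)
        stand = 100.0 * df.standing_time_s[band].sum() / max(df.standing_time_s.sum(), 1e-12)
        if df.steps.sum() == 0:
            walk = 0.0
        if df.standing_time_s.sum() == 0:
            stand = 0.0
        return walk, stand

    aw, as_ = rates(on)
    fw, fs = rates(off)
    return 0.5 * (aw + as_) - 0.5 * (fw + fs)


class TestOptimize:
    def test_separable_data_plateau_interior(self):
        rows = (
            [(0.3, 0, 15.0, "device_on")] * 10
            + [(2.5, 25, 0.0, "device_on")] * 10
            + [(0.0, 25, 0.0, "device_off")] * 10
            + [(0.0, 0, 15.0, "device_off")] * 10
        )
        grid = GridSpec(th_min_range=(0.0, 0.3), th_max_range=(0.3, 2.5), resolution=21)
        res = optimize_thresholds(_frame(rows), grid)
        assert res.objective_value == pytest.approx(100.0)
        assert 0.0 < res.thresholds.th_min < 0.3
        assert 0.3 < res.thresholds.th_max < 2.5
        # plateau midpoint: centered in the flat region
        assert res.thresholds.th_min == pytest.approx(0.15, abs=0.03)
        assert res.thresholds.th_max == pytest.approx(1.4, abs=0.15)

    def test_single_point_grid(self):
        rows = [(0.3, 0, 15.0, "device_on"), (2.5, 25, 0.0, "device_on")]
        grid = GridSpec(th_min_range=(0.1, 0.1), th_max_range=(1.0, 1.0), resolution=1)
        res = optimize_thresholds(_frame(rows), grid)
        assert res.thresholds == Thresholds(0.1, 1.0)

    def test_matches_brute_force_on_overlapping_instance(self):
        rng = np.random.default_rng(5)
        rows = []
        for _ in range(40):  # overlapping bands force a non-trivial optimum
            rows.append((float(rng.uniform(0.1, 1.4)), 0, 15.0, "device_on"))
            rows.append((float(rng.uniform(1.0, 3.0)), 25, 0.0, "device_on"))
            rows.append((float(rng.uniform(0.0, 2.0)), 25, 0.0, "device_off"))
            rows.append((float(rng.uniform(0.0, 2.0)), 0, 15.0, "device_off"))
        training = _frame(rows)
        grid = GridSpec(th_min_range=(0.0, 1.0), th_max_range=(1.0, 3.0), resolution=25)
        res = optimize_thresholds(training, grid)
        th_min_axis, th_max_axis = grid.axes()
        best = max(
            _brute_force_objective(training, a, b)
            for a in th_min_axis
            for b in th_max_axis
            if a < b
        )
        assert res.objective_value == pytest.approx(best, abs=1e-9)
        assert _brute_force_objective(
            training, res.thresholds.th_min, res.thresholds.th_max
        ) == pytest.approx(best, abs=1e-9)

    def test_objective_invariant_to_epoch_order(self):
        rng = np.random.default_rng(3)
        rows = [
            (float(rng.uniform(0, 3)), int(rng.integers(0, 30)), float(rng.uniform(0, 15)),
             "device_on" if rng.uniform() < 0.5 else "device_off")
            for _ in range(80)
        ]
        grid = GridSpec(th_min_range=(0.0, 0.5), th_max_range=(0.6, 2.5), resolution=15)
        a = optimize_thresholds(_frame(rows), grid)
        b = optimize_thresholds(_frame(rows[::-1]), grid)
        assert a.thresholds == b.thresholds
        assert np.allclose(a.objective, b.objective)

    def test_degenerate_grid_flagged(self):
        rows = [(0.0, 0, 15.0, "device_on")] * 4  # nothing classifiable anywhere
        grid = GridSpec(th_min_range=(0.5, 0.6), th_max_range=(1.0, 1.2), resolution=3)
        res = optimize_thresholds(_frame(rows), grid)
        assert res.degenerate


class TestTrainingSelection:
    def test_reproducible_subset(self):
        ids = [f"S{i:02d}" for i in range(1, 31)]
        a = select_training_subjects(ids, n=5, seed=42)
        b = select_training_subjects(ids, n=5, seed=42)
        assert a == b and len(a) == 5 and set(a) <= set(ids)

    def test_full_selection_is_identity(self):
        ids = ["a", "b", "c"]
        assert select_training_subjects(ids, n=3, seed=0) == sorted(ids)

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError):
            select_training_subjects(["a"], n=2, seed=0)


class TestThresholdRecovery:
    def test_recovered_thresholds_sit_inside_band_gap(self):
        """Over many seeded spike-free scenarios, calibrated thresholds fall
        below every standing-band V_avg and strictly inside the gap between
        the standing and walking bands observed across *all* subjects."""
        for seed in range(20):
            config = ScenarioConfig(
                n_subjects=5, seed=seed, n_high_noise_subjects=0, p_spike=0.0
            )
            ids = config.subject_ids()
            sessions = {
                sid: generate_inlab_session(config, i) for i, sid in enumerate(ids)
            }
            calib = calibrate_from_sessions(sessions, ids[:3], grid_resolution=41)
            th = calib["rcw"].thresholds
            stand_v, walk_v = [], []
            for session in sessions.values():
                for dev in session.devices.values():
                    df = dev.data
                    thigh = session.thigh.data
                    on = session.truth.worn["rcw"]
                    stand_mask = on & (thigh.standing_time_s > 0).to_numpy()
                    walk_mask = on & (thigh.steps > 0).to_numpy()
                    stand_v.extend(df.v_avg[stand_mask])
                    walk_v.extend(df.v_avg[walk_mask])
            assert th.th_min < min(stand_v), seed
            assert max(stand_v) < th.th_max < min(walk_v), seed

    def test_shared_thresholds_apply_to_both_devices(self):
        config = ScenarioConfig(n_subjects=4, seed=2, n_high_noise_subjects=0)
        ids = config.subject_ids()
        sessions = {sid: generate_inlab_session(config, i) for i, sid in enumerate(ids)}
        calib = calibrate_from_sessions(sessions, ids[:2], grid_resolution=31)
        assert calib["rcw"].thresholds == calib["lift"].thresholds
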