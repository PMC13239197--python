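import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from offload_adherence import (
    Thresholds,
    accuracy,
    adherent_totals,
    classify_epoch,
    classify_epochs,
    compute_v_avg,
    derive_standing_time,
    error_rate,
    vane_baseline_accuracy,
)
from offload_adherence.classify import CapabilityError

from conftest import make_classified_frame


class TestVAvg:
    @pytest.mark.parametrize(
        "xyz,expected",
        [((0.0, 0.0, 0.0), 0.0), ((0.2, 0.4, 0.6), 0.4), ((0.6, 0.2, 0.4), 0.4)],
    )
    def test_mean_of_axes(self, xyz, expected):
        assert compute_v_avg(*xyz) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            compute_v_avg(-0.1, 0.2, 0.3)

    @given(st.lists(st.floats(0, 10), min_size=3, max_size=3))
    def test_permutation_invariant_and_bounded(self, xyz):
        v = compute_v_avg(*xyz)
        assert v == pytest.approx(compute_v_avg(*reversed(xyz)))
        assert min(xyz) - 1e-12 <= v <= max(xyz) + 1e-12


class TestStandingTime:
    @pytest.mark.parametrize(
        "upright,walking,expected", [(15, 15, 0), (15, 0, 15), (10, 4, 6)]
    )
    def test_upright_minus_walking(self, upright, walking, expected):
        assert derive_standing_time(upright, walking) == expected

    def test_walking_exceeding_upright_rejected(self):
        with pytest.raises(ValueError):
            derive_standing_time(10, 11)


class TestClassifyEpoch:
    def test_walking_use_attributes_all_epoch_steps(self, thresholds):
        out = classify_epoch(steps=25, standing_time=0.0, v_avg=2.0, thresholds=thresholds)
        assert out["device_used_walking"] and not out["device_used_standing"]
        assert out["attributed_steps"] == 25

    def test_zero_variance_is_non_use(self, thresholds):
        out = classify_epoch(steps=25, standing_time=15.0, v_avg=0.0, thresholds=thresholds)
        assert not out["device_used_walking"] and not out["device_used_standing"]
        assert out["attributed_steps"] == 0 and out["attributed_standing_s"] == 0.0

    def test_standing_band_attributes_standing_seconds(self, thresholds):
        out = classify_epoch(steps=0, standing_time=15.0, v_avg=0.5, thresholds=thresholds)
        assert out["device_used_standing"]
        assert out["attributed_standing_s"] == 15.0

    @pytest.mark.parametrize("v", [0.2, 1.0])
    def test_threshold_boundaries_are_exclusive(self, thresholds, v):
        out = classify_epoch(steps=10, standing_time=5.0, v_avg=v, thresholds=thresholds)
        # v equal to a threshold falls in neither band
        if v == thresholds.th_min:
            assert not out["device_used_standing"]
        if v == thresholds.th_max:
            assert not out["device_used_standing"] and not out["device_used_walking"]

    def test_absent_epochs_excluded(self, thresholds):
        df = pd.DataFrame(
            {
                "steps": [10, 10],
                "standing_time_s": [0.0, 0.0],
                "v_avg": [2.0, np.nan],
                "present": [True, False],
            }
        )
        out = classify_epochs(df, thresholds)
        assert list(out["attributed_steps"]) == [10, 0]

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            Thresholds(1.0, 0.5)


class TestTotalsAndAccuracy:
    def test_summation(self, thresholds):
        frame = make_classified_frame(
            [(25, 0.0, 2.0), (0, 15.0, 0.0), (20, 0.0, 3.0)], thresholds
        )
        sc_aa, st_aa = adherent_totals(frame)
        assert sc_aa == 45 and st_aa == 0.0

    def test_empty_input(self, thresholds):
        sc_aa, st_aa = adherent_totals(make_classified_frame([], thresholds))
        assert (sc_aa, st_aa) == (0, 0.0)

    def test_perfect_and_partial_accuracy(self, thresholds):
        frame = make_classified_frame(
            [(25, 0.0, 2.0), (15, 0.0, 2.0), (0, 10.0, 0.5), (0, 10.0, 0.0)], thresholds
        )
        acc_steps, acc_stand = accuracy(frame)
        assert acc_steps == pytest.approx(100.0)
        assert acc_stand == pytest.approx(50.0)

    def test_empty_denominator_is_not_applicable(self, thresholds):
        frame = make_classified_frame([(10, 0.0, 2.0)], thresholds)
        _, acc_stand = accuracy(frame)
        assert acc_stand is None


class TestErrorRate:
    def _toy(self, thresholds):
        # six-epoch table exercising both error components
        rows = [
            (20, 0.0, 2.0, {"vane_steps": 0.0, "vane_walking_time_s": 0.0, "vane_upright_time_s": 0.0}),  # off, false walking attribution
            (0, 10.0, 0.5, {"vane_steps": 0.0, "vane_walking_time_s": 0.0, "vane_upright_time_s": 0.0}),  # off, false standing attribution
            (0, 0.0, 2.0, {"vane_steps": 5.0, "vane_walking_time_s": 10.0, "vane_upright_time_s": 10.0}),  # on, phantom steps
            (0, 0.0, 0.5, {"vane_steps": 0.0, "vane_walking_time_s": 0.0, "vane_upright_time_s": 4.0}),  # on, phantom standing
            (30, 0.0, 2.0, {"vane_steps": 28.0, "vane_walking_time_s": 14.0, "vane_upright_time_s": 15.0}),  # on, correct
            (0, 15.0, 0.5, {"vane_steps": 0.0, "vane_walking_time_s": 0.0, "vane_upright_time_s": 14.0}),  # on, correct
        ]
        frame = make_classified_frame(rows, thresholds)
        condition = pd.Series(
            ["device_off", "device_off", "device_on", "device_on", "device_on", "device_on"]
        )
        return frame, condition

    def test_two_component_error_hand_summed(self, thresholds):
        # numerator steps: 20 (off) + 5 (phantom VANE) = 25 of 50 total -> 50%
        # numerator standing: 10 (off) + 4 (phantom VANE) = 14 of 25 total -> 56%
        frame, condition = self._toy(thresholds)
        err_steps, err_stand = error_rate(frame, condition)
        assert err_steps == pytest.approx(50.0)
        assert err_stand == pytest.approx(56.0)

    def test_perfect_classifier_zero_error(self, thresholds):
        rows = [
            (20, 0.0, 0.0),  # off, stationary device
            (0, 10.0, 0.0),
            (30, 0.0, 2.0),  # on, worn
            (0, 15.0, 0.5),
        ]
        frame = make_classified_frame(rows, thresholds)
        condition = pd.Series(["device_off", "device_off", "device_on", "device_on"])
        assert error_rate(frame, condition) == (pytest.approx(0.0), pytest.approx(0.0))


class TestVaneBaseline:
    def test_ratio_including_overcount(self, thresholds):
        rows = [
            (10, 5.0, 2.0, {"vane_steps": 20.0, "vane_walking_time_s": 0.0, "vane_upright_time_s": 0.0}),
        ]
        frame = make_classified_frame(rows, thresholds)
        condition = pd.Series(["device_on"])
        pct_steps, pct_stand = vane_baseline_accuracy(frame, condition)
        assert pct_steps == pytest.approx(200.0)
        assert pct_stand == pytest.approx(0.0)

    def test_missing_vane_columns(self, thresholds):
        frame = make_classified_frame([(10, 0.0, 2.0)], thresholds)
        with pytest.raises(CapabilityError):
            vane_baseline_accuracy(frame, pd.Series(["device_on"]))


@st.composite
def epoch_sets(draw):
    n = draw(st.integers(1, 60))
    steps = draw(st.lists(st.integers(0, 40), min_size=n, max_size=n))
    standing = draw(st.lists(st.floats(0, 15), min_size=n, max_size=n))
    v = draw(st.lists(st.floats(0, 5), min_size=n, max_size=n))
    return list(zip(steps, standing, v))


class TestInvariants:
    @given(epoch_sets(), st.floats(0.1, 0.5), st.floats(1.0, 3.0))
    def test_lowering_th_max_never_decreases_step_count(self, rows, th_min, th_max):
        lo = make_classified_frame(rows, Thresholds(th_min, th_max * 0.75))
        hi = make_classified_frame(rows, Thresholds(th_min, th_max))
        assert adherent_totals(lo)[0] >= adherent_totals(hi)[0]

    @given(epoch_sets(), st.floats(0.1, 0.5), st.floats(1.0, 3.0))
    def test_raising_th_min_never_increases_standing(self, rows, th_min, th_max):
        lo = make_classified_frame(rows, Thresholds(th_min, th_max))
        hi = make_classified_frame(rows, Thresholds(th_min * 1.5, th_max))
        assert adherent_totals(hi)[1] <= adherent_totals(lo)[1]

    @given(epoch_sets())
    def test_conservation_of_steps_and_standing(self, rows):
        frame = make_classified_frame(rows, Thresholds(0.2, 1.0))
        sc_aa, st_aa = adherent_totals(frame)
        unattr_steps = int(frame["steps"].sum()) - sc_aa
        unattr_stand = float(frame["standing_time_s"].sum()) - st_aa
        assert unattr_steps >= 0 and unattr_stand >= -1e-9
        assert sc_aa + unattr_steps == int(frame["steps"].sum())

    @given(epoch_sets())
    def test_totals_match_per_epoch_recount(self, rows):
        th = Thresholds(0.2, 1.0)
        frame = make_classified_frame(rows, th)
        # independent per-epoch re-count
        sc, st_ = 0, 0.0
        for steps, standing, v in rows:
            if v > th.th_max and steps > 0:
                sc += steps
            if th.th_min < v < th.th_max and standing > 0:
                st_ += standing
        assert adherent_totals(frame) == (sc, pytest.approx(st_))
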