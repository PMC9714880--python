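"""Trajectory-to-behavior reduction: velocity-rule RT, change-of-mind
detection, exclusion rules, stop psychometrics, and group statistics —
tested on closed-form synthetic trajectories, independent of the simulator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from actionreg import metrics
from actionreg.errors import MetricError
from actionreg.metrics import (Trajectory, compute_rt, detect_change_of_mind,
                               filter_trials, generate_synthetic_trajectory,
                               group_stats, minimum_jerk_rt_offset,
                               stop_probability_curve)


class TestComputeRt:
    def test_stationary_returns_absent(self):
        traj = generate_synthetic_trajectory("stationary")
        assert compute_rt(traj) is None

    @pytest.mark.parametrize("onset", [200.0, 300.0, 450.0])
    def test_minimum_jerk_matches_analytic_crossing(self, onset):
        """RT equals onset + the closed-form 10%-of-peak crossing offset,
        within one sample."""
        dt = 5.0
        traj = generate_synthetic_trajectory(
            "minimum_jerk", {"onset_ms": onset, "duration_ms": 600.0, "dt_ms": dt})
        expected = onset + minimum_jerk_rt_offset(600.0)
        assert compute_rt(traj) == pytest.approx(expected, abs=dt)

    def test_time_shift_equivariance(self):
        base = generate_synthetic_trajectory("minimum_jerk", {"onset_ms": 300.0})
        shifted = Trajectory(times=base.times + 120.0, positions=base.positions)
        rt0 = compute_rt(base)
        rt1 = compute_rt(shifted)
        assert rt1 == pytest.approx(rt0 + 120.0, abs=1e-9)

    @settings(deadline=None, derandomize=True)
    @given(scale=st.floats(1e-3, 1e3))
    def test_spatial_scale_invariance(self, scale):
        """The 10% rule is relative, so uniform spatial scaling leaves RT
        unchanged."""
        base = generate_synthetic_trajectory("minimum_jerk", {"onset_ms": 250.0})
        scaled = Trajectory(times=base.times, positions=base.positions * scale)
        assert compute_rt(scaled) == compute_rt(base)

    def test_too_few_samples_is_metric_error(self):
        with pytest.raises(MetricError):
            Trajectory(times=np.array([0.0, 1.0, 2.0]), positions=np.zeros((3, 2)))

    def test_non_monotone_times_rejected(self):
        with pytest.raises(MetricError):
            Trajectory(times=np.array([0.0, 2.0, 1.0, 3.0]), positions=np.zeros((4, 2)))


class TestChangeOfMind:
    def test_monotone_reach_is_not_change_of_mind(self):
        traj = generate_synthetic_trajectory("minimum_jerk", {"amplitude": 1.0})
        assert not detect_change_of_mind(traj, range_extent=2.0)

    def test_excursion_past_criterion_with_opposite_arrival(self):
        traj = generate_synthetic_trajectory(
            "change_of_mind", {"excursion_frac": 0.06, "range_extent": 2.0})
        assert detect_change_of_mind(traj, range_extent=2.0)

    def test_excursion_below_criterion_is_not_flagged(self):
        traj = generate_synthetic_trajectory(
            "change_of_mind", {"excursion_frac": 0.04, "range_extent": 2.0})
        assert not detect_change_of_mind(traj, range_extent=2.0)

    def test_final_direction_override(self):
        traj = generate_synthetic_trajectory("minimum_jerk", {"amplitude": 1.0})
        # hand went right; a (hypothetical) final left response makes the
        # rightward excursion a change of mind
        assert detect_change_of_mind(traj, range_extent=2.0, final_direction="left")


def _table(rts, com=None, **cols):
    n = len(rts)
    base = {"task": ["decision"] * n, "group": ["neurotypical"] * n,
            "trial_type": ["instructed"] * n, "rt_ms": rts,
            "change_of_mind": com or [False] * n,
            "stop_outcome": ["n/a"] * n, "ssd": [None] * n}
    base.update(cols)
    return pd.DataFrame(base)


class TestFilterTrials:
    def test_toy_table_worked_example(self):
        """The printed six-value example: {90, 150, 400, 600, 1600, 420}
        keeps exactly {150, 400, 600, 420}."""
        df = _table([90.0, 150.0, 400.0, 600.0, 1600.0, 420.0])
        analyzed, report = filter_trials(df)
        assert sorted(analyzed["rt_ms"]) == [150.0, 400.0, 420.0, 600.0]
        assert report["rt_below_100"] == 1
        assert report["rt_above_1500"] == 1
        assert report["rt_outlier_3sd"] == 0

    def test_identical_rts_not_removed_by_sd_rule(self):
        analyzed, report = filter_trials(_table([400.0] * 8))
        assert len(analyzed) == 8
        assert report["rt_outlier_3sd"] == 0

    def test_change_of_mind_trials_removed(self):
        df = _table([300.0, 310.0, 320.0], com=[False, True, False])
        analyzed, report = filter_trials(df)
        assert len(analyzed) == 2
        assert report["change_of_mind"] == 1

    def test_empty_table(self):
        analyzed, report = filter_trials(_table([]))
        assert analyzed.empty
        assert sum(report.values()) == 0

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.one_of(st.none(), st.floats(0, 2000)), max_size=40))
    def test_exclusion_accounting_reconciles(self, rts):
        df = _table(rts)
        analyzed, report = filter_trials(df)
        assert len(df) == len(analyzed) + sum(report.values())


class TestStopCurve:
    def _stops(self, rows):
        return pd.DataFrame(rows, columns=["ssd", "stop_outcome"]).assign(
            task="stop_signal", group="neurotypical", trial_type="stop")

    def test_all_successful_gives_ones(self):
        df = self._stops([(100.0, "success")] * 4 + [(150.0, "success")] * 3)
        curve = stop_probability_curve(df)
        assert np.all(curve["p_stop"] == 1.0)

    def test_ratio_definition(self):
        df = self._stops([(200.0, "success")] * 3 + [(200.0, "fail")])
        curve = stop_probability_curve(df)
        assert curve.loc[0, "p_stop"] == pytest.approx(0.75)
        assert curve.loc[0, "n"] == 4

    def test_values_bounded(self):
        rng = np.random.default_rng(2)
        df = self._stops([(50.0 * rng.integers(0, 8),
                           "success" if rng.random() < 0.5 else "fail")
                          for _ in range(100)])
        curve = stop_probability_curve(df)
        assert ((curve["p_stop"] >= 0) & (curve["p_stop"] <= 1)).all()

    def test_no_stop_trials_is_error(self):
        with pytest.raises(MetricError):
            stop_probability_curve(_table([300.0]))


class TestGroupStats:
    def test_identical_samples_null_ttest(self):
        a = np.linspace(300, 500, 50)
        t, p = metrics.ttest_rt(a, a.copy())
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_extreme_separation(self):
        rng = np.random.default_rng(0)
        a = rng.normal(300, 10, 50)
        b = rng.normal(400, 10, 50)   # means 10 SDs apart
        _, p = metrics.ttest_rt(a, b)
        assert p < 1e-10

    def test_anova_pure_main_effect_has_null_interaction(self):
        """A 2x2 table with identical condition effects in both groups has
        an interaction term of (numerically) zero."""
        rows = []
        jitter = [-2.0, -1.0, 1.0, 2.0]
        for group in ("neurotypical", "pd"):
            for cond, mean in (("instructed", 300.0), ("choice", 360.0)):
                for j in jitter:
                    rows.append({"task": "decision", "group": group,
                                 "trial_type": cond, "rt_ms": mean + j})
        table = group_stats(pd.DataFrame(rows))["anova_decision"]
        inter = table.loc["C(group):C(trial_type)"]
        assert inter["F"] == pytest.approx(0.0, abs=1e-9)
        cond_row = table.loc["C(trial_type)"]
        assert cond_row["PR(>F)"] < 1e-12

    def test_go_trial_group_ttest_present(self):
        rng = np.random.default_rng(1)
        rows = []
        for group, mu in (("neurotypical", 450.0), ("pd", 380.0)):
            for rt in rng.normal(mu, 40, 30):
                rows.append({"task": "stop_signal", "group": group,
                             "trial_type": "go", "rt_ms": rt})
        out = group_stats(pd.DataFrame(rows))
        assert out["ttest_go_groups"]["p"] < 1e-6
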