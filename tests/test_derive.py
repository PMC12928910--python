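"""Windowing, rescue-window merging, imputation rule order, AUC and the
population definitions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paintrial.config import Trajectory, TrialConfig
from paintrial.derive import (
    DerivationError,
    assign_windows,
    build_populations,
    build_rescue_windows,
    compute_auc,
    consumption,
    derive_trial,
    impute_series,
    multiple_impute,
    time_to_first_rescue,
)
from paintrial.simulate import simulate_trial

SCHEDULE = TrialConfig().schedule_hours


def _pain(rows):
    return pd.DataFrame(rows, columns=["subject_id", "time_h", "score", "context"])


def _series(pain, subjects=None):
    return assign_windows(pain, SCHEDULE, subjects=subjects)


def riemann_auc(times, values, through, dt=1e-4):
    """Independent midpoint-Riemann oracle on the piecewise-linear curve."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    order = np.argsort(t)
    t, v = t[order], v[order]
    n = max(int(round(through / dt)), 1)
    step = through / n
    mid = (np.arange(n) + 0.5) * step
    return float(np.interp(mid, t, v).sum() * step)


class TestAssignWindows:
    def test_exact_hit_assigned_to_its_nominal_hour(self):
        s = _series(_pain([("a", 6.0, 5, "scheduled")]))
        assert s.values.loc["a", 6.0] == 5
        assert s.provenance.loc["a", 6.0] == "observed"
        assert s.actual_time.loc["a", 6.0] == 6.0

    def test_closest_in_absolute_time_wins(self):
        # window for nominal 6 is (5, 7]; 6.4 is closer than 5.2
        s = _series(
            _pain([("a", 5.2, 3, "scheduled"), ("a", 6.4, 8, "scheduled")])
        )
        assert s.values.loc["a", 6.0] == 8
        assert s.values.loc["a", 4.0] != s.values.loc["a", 4.0] or True

    def test_equidistant_tie_keeps_earlier_observation(self):
        s = _series(
            _pain([("a", 5.5, 3, "scheduled"), ("a", 6.5, 8, "scheduled")])
        )
        # both are 0.5 h from nominal 6; enumerating both candidates shows
        # only the tie-break separates them, and the earlier one is kept
        assert abs(5.5 - 6.0) == abs(6.5 - 6.0)
        assert s.values.loc["a", 6.0] == 3

    def test_unobserved_hours_flagged_missing(self):
        s = _series(_pain([("a", 6.0, 5, "scheduled")]))
        assert s.provenance.loc["a", 0.0] == "missing"
        assert np.isnan(s.values.loc["a", 0.0])

    def test_pre_dose_and_negative_times_excluded(self):
        s = _series(
            _pain([("a", -1.0, 2, "pre_dose"), ("a", 0.05, 4, "scheduled")])
        )
        assert s.values.loc["a", 0.0] == 4
        assert (s.provenance.loc["a"] == "observed").sum() == 1

    def test_unsorted_schedule_rejected(self):
        with pytest.raises(DerivationError, match="increasing"):
            assign_windows(_pain([("a", 1.0, 1, "scheduled")]), (0, 2, 1, 72))


class TestRescueWindows:
    def test_acetaminophen_window_is_six_hours_with_prior_carry(self):
        pain = _pain([("a", 9.5, 7, "scheduled"), ("a", 10.0, 7, "pre_rescue")])
        rescue = pd.DataFrame(
            [("a", "acetaminophen", 1000.0, 10.0)],
            columns=["subject_id", "drug", "dose_mg", "time_h"],
        )
        w = build_rescue_windows(rescue, pain)
        assert len(w) == 1
        row = w.iloc[0]
        assert (row["start_h"], row["end_h"], row["carry_score"]) == (10.0, 16.0, 7.0)

    def test_chained_windows_merge_to_maximum_end(self):
        pain = _pain([("a", 10.0, 7, "pre_rescue")])
        rescue = pd.DataFrame(
            [
                ("a", "tramadol", 50.0, 10.0),      # window (10, 14]
                ("a", "acetaminophen", 1000.0, 12.0),  # extends to 18
            ],
            columns=["subject_id", "drug", "dose_mg", "time_h"],
        )
        w = build_rescue_windows(rescue, pain)
        assert len(w) == 1
        assert (w.iloc[0]["start_h"], w.iloc[0]["end_h"]) == (10.0, 18.0)
        assert w.iloc[0]["n_events"] == 2

    def test_separated_doses_stay_disjoint(self):
        pain = _pain([("a", 1.0, 6, "scheduled")])
        rescue = pd.DataFrame(
            [("a", "acetaminophen", 1000.0, 2.0), ("a", "acetaminophen", 1000.0, 10.0)],
            columns=["subject_id", "drug", "dose_mg", "time_h"],
        )
        w = build_rescue_windows(rescue, pain)
        assert len(w) == 2
        assert w.iloc[0]["end_h"] <= w.iloc[1]["start_h"]

    def test_rescue_without_prior_observation_names_subject(self):
        rescue = pd.DataFrame(
            [("ghost", "tramadol", 50.0, 1.0)],
            columns=["subject_id", "drug", "dose_mg", "time_h"],
        )
        with pytest.raises(DerivationError, match="ghost"):
            build_rescue_windows(rescue, _pain([]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        times=st.lists(
            st.floats(min_value=0.5, max_value=60, allow_nan=False), min_size=1,
            max_size=8,
        ),
        drugs=st.lists(st.sampled_from(["acetaminophen", "tramadol"]), min_size=8,
                       max_size=8),
    )
    def test_merging_never_shortens_and_windows_disjoint(self, times, drugs):
        times = sorted(times)
        pain = _pain([("a", 0.0, 5, "scheduled")])
        rescue = pd.DataFrame(
            {
                "subject_id": "a",
                "drug": drugs[: len(times)],
                "dose_mg": 50.0,
                "time_h": times,
            }
        )
        w = build_rescue_windows(rescue, pain).sort_values("start_h")
        lengths = {"acetaminophen": 6.0, "tramadol": 4.0}
        for t, d in zip(times, rescue["drug"]):
            covering = w[(w["start_h"] <= t) & (w["end_h"] >= t + lengths[d])]
            assert len(covering) == 1  # every member window fully inside a merge
        starts = w["start_h"].to_numpy()
        ends = w["end_h"].to_numpy()
        assert (starts[1:] >= ends[:-1]).all()


def _one_subject_series(values):
    pain = _pain(
        [("a", h, v, "scheduled") for h, v in zip(SCHEDULE, values) if v is not None]
    )
    return _series(pain, subjects=["a", "b"])


class TestImputeSeries:
    ARM = pd.Series({"a": "high", "b": "high"})

    def _full_arm(self):
        # subject b fully observed at constant 6 so arm medians exist
        return _pain([("b", h, 6, "scheduled") for h in SCHEDULE])

    def test_leading_missing_takes_arm_median(self):
        pain = pd.concat(
            [
                _pain([("a", h, 7, "scheduled") for h in SCHEDULE[1:]]),
                self._full_arm(),
            ]
        )
        s = _series(pain)
        out = impute_series(s, pd.DataFrame(), pd.DataFrame(), self.ARM)
        assert out.values.loc["a", 0.0] == 6  # median of {6} at hour 0
        assert out.provenance.loc["a", 0.0] == "median_pre_first"

    def test_loe_discontinuation_carries_worst_prior_value(self):
        vals = [2, 3, 8, 5, 4] + [4] * 15
        pain = pd.concat([_one_subject_pain(vals[:6]), self._full_arm()])
        events = pd.DataFrame(
            [("a", "loe_discontinuation", 24.0)],
            columns=["subject_id", "kind", "time_h"],
        )
        s = _series(pain)
        out = impute_series(s, pd.DataFrame(), events, self.ARM)
        hours = out.hours
        after = out.values.loc["a"].to_numpy()[hours >= 24.0]
        assert (after == 8).all()
        assert (out.provenance.loc["a"].to_numpy()[hours >= 24.0] == "wocf").all()

    def test_fully_observed_series_unchanged(self):
        pain = pd.concat(
            [_pain([("a", h, 5, "scheduled") for h in SCHEDULE]), self._full_arm()]
        )
        s = _series(pain)
        out = impute_series(s, pd.DataFrame(), pd.DataFrame(), self.ARM)
        pd.testing.assert_frame_equal(out.values, s.values)
        pd.testing.assert_frame_equal(out.provenance, s.provenance)

    def test_rescue_override_beats_observed_value_and_precedes_locf(self):
        pain = pd.concat(
            [
                _pain(
                    [("a", 0.0, 6, "scheduled"), ("a", 10.0, 7, "pre_rescue"),
                     ("a", 12.0, 2, "scheduled")]
                ),
                self._full_arm(),
            ]
        )
        windows = pd.DataFrame(
            [("a", 10.0, 16.0, 7.0, 1)],
            columns=["subject_id", "start_h", "end_h", "carry_score", "n_events"],
        )
        s = _series(pain)
        out = impute_series(s, windows, pd.DataFrame(), self.ARM)
        # observed 2 at hour 12 lies inside the (10, 16] window: replaced by 7
        assert out.values.loc["a", 12.0] == 7
        assert out.provenance.loc["a", 12.0] == "rescue_window"
        # LOCF beyond the window carries the carry score, not the masked 2
        assert out.values.loc["a", 20.0] == 7
        assert out.provenance.loc["a", 20.0] == "locf"

    def test_withdrawal_cells_flagged_for_multiple_imputation(self):
        pain = pd.concat(
            [_pain([("a", h, 5, "scheduled") for h in SCHEDULE if h < 30]),
             self._full_arm()],
        )
        events = pd.DataFrame(
            [("a", "withdrawal_other", 30.0)],
            columns=["subject_id", "kind", "time_h"],
        )
        s = _series(pain)
        out = impute_series(s, pd.DataFrame(), events, self.ARM)
        hours = out.hours
        assert (out.provenance.loc["a"].to_numpy()[hours >= 30] == "mi_pending").all()
        assert out.values.loc["a"].isna().to_numpy()[hours >= 30].all()

    def test_imputation_is_idempotent_on_simulated_trials(self):
        cfg = TrialConfig(n_per_arm=25, n_sites=2)
        trial = simulate_trial(cfg, seed=77)
        arm_of = trial.roster.set_index("subject_id")["arm"]
        s = assign_windows(trial.pain, cfg.schedule_hours,
                           subjects=trial.roster["subject_id"])
        w = build_rescue_windows(trial.rescue, trial.pain, cfg)
        once = impute_series(s, w, trial.events, arm_of)
        twice = impute_series(once, w, trial.events, arm_of)
        pd.testing.assert_frame_equal(once.values, twice.values)
        pd.testing.assert_frame_equal(once.provenance, twice.provenance)


def _one_subject_pain(values):
    return _pain(
        [("a", h, v, "scheduled") for h, v in zip(SCHEDULE, values) if v is not None]
    )


class TestMultipleImpute:
    ARM = pd.Series({"a": "high", "b": "high", "c": "high"})

    def test_no_flagged_cells_returns_identical_copies(self):
        pain = pd.concat(
            [_pain([(s, h, 5, "scheduled") for h in SCHEDULE]) for s in "abc"]
        )
        s = _series(pain)
        done = impute_series(s, pd.DataFrame(), pd.DataFrame(), self.ARM)
        out, datasets = multiple_impute(done, self.ARM, n_imputations=5, seed=1)
        assert len(datasets) == 5
        for d in datasets:
            pd.testing.assert_frame_equal(d, done.values)
        pd.testing.assert_frame_equal(out.values, done.values)

    def test_identical_donors_give_deterministic_imputation(self):
        rows = []
        for sid in ("b", "c", "d", "e"):
            rows += [(sid, h, 4, "scheduled") for h in SCHEDULE]
        rows += [("a", h, 4, "scheduled") for h in SCHEDULE if h < 72]
        pain = _pain(rows)
        arm = pd.Series({s: "high" for s in "abcde"})
        s = _series(pain)
        events = pd.DataFrame(
            [("a", "withdrawal_other", 70.0)],
            columns=["subject_id", "kind", "time_h"],
        )
        done = impute_series(s, pd.DataFrame(), events, arm)
        out, _ = multiple_impute(done, arm, n_imputations=20, seed=3)
        # all donors equal 4 -> zero residual variance -> imputed mean is 4
        assert out.values.loc["a", 72.0] == pytest.approx(4.0)
        assert out.provenance.loc["a", 72.0] == "mi_mean"

    def test_mar_holes_recover_arm_timepoint_means(self):
        """20% missing-at-random withdrawals: per-cell MI means stay close
        to the generating arm mean at that timepoint."""
        cfg = TrialConfig(n_per_arm=150, n_sites=1, dropout_rates={},
                          rescue_hazard_base=0.0, missing_hour0_prob=0.0,
                          sporadic_missing_prob=0.0)
        trial = simulate_trial(cfg, seed=5)
        arm_of = trial.roster.set_index("subject_id")["arm"]
        s = assign_windows(trial.pain, cfg.schedule_hours,
                           subjects=trial.roster["subject_id"])
        rng = np.random.default_rng(8)
        subjects = s.values.index.to_numpy()
        hit = rng.random(len(subjects)) < 0.20
        events = pd.DataFrame(
            {
                "subject_id": subjects[hit],
                "kind": "withdrawal_other",
                "time_h": 70.0,
            }
        )
        masked = s.copy()
        vm = masked.values.to_numpy()
        pm = masked.provenance.to_numpy(dtype=object)
        late = masked.hours >= 70.0
        vm[np.ix_(hit, late)] = np.nan
        pm[np.ix_(hit, late)] = "missing"
        masked.values = pd.DataFrame(vm, index=s.values.index, columns=s.values.columns)
        masked.provenance = pd.DataFrame(pm, index=s.values.index,
                                         columns=s.values.columns)
        done = impute_series(masked, pd.DataFrame(), events, arm_of)
        out, _ = multiple_impute(done, arm_of, n_imputations=20, seed=9)
        # per-cell deviations share the regression-estimation error of the
        # ~120 donors (SD about 0.3 per cell of ~30 masked subjects), so
        # cells get a loose guard while the across-arm pooled deviation
        # must stay within 0.3 NPRS
        pooled = []
        for arm in cfg.effect_model:
            ids = arm_of[arm_of == arm].index
            rows = out.values.index.isin(ids) & hit
            if rows.sum() < 10:
                continue
            cell_mean = out.values.loc[rows, 72.0].mean()
            truth = s.values.loc[np.array(rows), 72.0].mean()  # pre-mask scores
            assert abs(cell_mean - truth) < 1.0
            pooled.append(cell_mean - truth)
        assert abs(np.mean(pooled)) < 0.3


class TestComputeAuc:
    def test_constant_five_through_48_gives_240(self):
        hours = np.array(SCHEDULE)
        assert compute_auc(hours, np.full(len(hours), 5.0), 48) == pytest.approx(240.0)

    def test_all_zero_scores_give_zero(self):
        hours = np.array(SCHEDULE)
        assert compute_auc(hours, np.zeros(len(hours)), 72) == pytest.approx(0.0)

    def test_piecewise_example_matches_fine_grid_oracle(self):
        t = [0, 1, 3, 4]
        v = [8, 6, 7, 4]
        oracle = riemann_auc(t, v, 4)
        assert oracle == pytest.approx(25.5, abs=1e-3)
        assert compute_auc(t, v, 4) == pytest.approx(oracle, rel=1e-6)

    def test_bad_through_hour_rejected(self):
        with pytest.raises(DerivationError):
            compute_auc([0, 72], [1, 1], 0)
        with pytest.raises(DerivationError):
            compute_auc([0, 72], [1, 1], 80)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_riemann_oracle_on_random_series(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 15)
        t = np.sort(rng.uniform(0, 72, n))
        t[0] = 0.0
        v = rng.uniform(0, 10, n)
        through = float(rng.uniform(t[1] if n > 1 else 1.0, t[-1]))
        if not 0 < through <= 72:
            return
        auc = compute_auc(t, v, through)
        assert auc == pytest.approx(riemann_auc(t, v, through), rel=1e-6, abs=1e-6)
        assert 0 <= auc <= 10 * through

    def test_additive_over_interval_split_at_observation_point(self):
        rng = np.random.default_rng(4)
        t = np.sort(np.append(rng.uniform(0, 48, 10), [0.0, 24.0, 48.0]))
        v = rng.uniform(0, 10, len(t))
        full = compute_auc(t, v, 48)
        first = compute_auc(t, v, 24)
        second = riemann_auc(t, v, 48) - riemann_auc(t, v, 24)
        assert full == pytest.approx(first + second, rel=1e-6)

    def test_spi_monotone_in_through_hour(self):
        t = np.array(SCHEDULE)
        rng = np.random.default_rng(11)
        v = rng.uniform(0, 10, len(t))
        aucs = [compute_auc(t, v, h) for h in (24, 48, 72)]
        assert aucs[0] <= aucs[1] <= aucs[2]


class TestConsumptionAndTimeToRescue:
    def _rescue(self, rows):
        return pd.DataFrame(rows, columns=["subject_id", "drug", "dose_mg", "time_h"])

    def test_no_events_gives_zero_totals(self):
        out = consumption(self._rescue([]), (0, 48), 0.1, subjects=["a"])
        row = out.iloc[0]
        assert (row["acetaminophen_mg"], row["tramadol_mg"], row["tramadol_meq_mg"]) \
            == (0.0, 0.0, 0.0)

    def test_tramadol_meq_uses_configured_factor(self):
        rescue = self._rescue(
            [("a", "tramadol", 50.0, t) for t in (1.0, 6.0, 11.0)]
        )
        out = consumption(rescue, (0, 48), 0.1).set_index("subject_id")
        assert out.loc["a", "tramadol_mg"] == 150.0
        assert out.loc["a", "tramadol_meq_mg"] == pytest.approx(15.0)

    def test_interval_is_half_open_at_the_end(self):
        rescue = self._rescue(
            [("a", "acetaminophen", 1000.0, 47.999), ("a", "acetaminophen", 1000.0, 48.0)]
        )
        out = consumption(rescue, (0, 48), 0.1).set_index("subject_id")
        assert out.loc["a", "acetaminophen_mg"] == 1000.0

    def test_first_rescue_time_and_censoring(self):
        roster = pd.DataFrame(
            {
                "subject_id": ["a", "b", "c", "d"],
                "had_surgery": [True, True, True, False],
            }
        )
        rescue = self._rescue(
            [("a", "tramadol", 50.0, 4.0), ("a", "tramadol", 50.0, 10.0),
             ("c", "tramadol", 50.0, 80.0)]
        )
        out = time_to_first_rescue(rescue, roster).set_index("subject_id")
        assert out.loc["a", "time_h"] == 4.0 and out.loc["a", "event"] == 1
        assert out.loc["b", "time_h"] == 72.0 and out.loc["b", "event"] == 0
        # first use after 72 h is censored at 72
        assert out.loc["c", "time_h"] == 72.0 and out.loc["c", "event"] == 0
        assert "d" not in out.index  # no surgery


class TestPopulations:
    def _roster(self, **cols):
        base = {
            "subject_id": ["a", "b", "c"],
            "had_surgery": [True] * 3,
            "dosed": [True] * 3,
            "major_deviation": [False] * 3,
        }
        base.update(cols)
        return pd.DataFrame(base)

    def test_never_dosed_subject_is_itt_but_not_mitt(self):
        roster = self._roster(dosed=[False, True, True])
        pain = _pain([(s, 1.0, 5, "scheduled") for s in "abc"])
        pops = build_populations(roster, pain).set_index("subject_id")
        assert pops.loc["a", "itt"] and not pops.loc["a", "mitt"]

    def test_no_post_surgery_score_excluded_from_mitt(self):
        roster = self._roster()
        pain = _pain([("a", -1.0, 2, "pre_dose"), ("b", 1.0, 5, "scheduled"),
                      ("c", 1.0, 5, "scheduled")])
        pops = build_populations(roster, pain).set_index("subject_id")
        assert not pops.loc["a", "mitt"] and pops.loc["b", "mitt"]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 5000))
    def test_population_nesting_always_holds(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        roster = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "had_surgery": rng.random(n) > 0.1,
                "dosed": rng.random(n) > 0.2,
                "major_deviation": rng.random(n) < 0.2,
            }
        )
        with_obs = rng.random(n) > 0.15
        pain = _pain(
            [(f"s{i}", 1.0, 5, "scheduled") for i in range(n) if with_obs[i]]
        )
        pops = build_populations(roster, pain)
        assert (~pops["pps"] | pops["mitt"]).all()
        assert (~pops["mitt"] | pops["itt"]).all()


class TestDeriveTrialInvariants:
    def test_noise_free_event_free_spi_equals_closed_form_trapezoid(self, quiet_config):
        cfg = quiet_config.replace(n_per_arm=3)
        trial = simulate_trial(cfg, seed=1)
        # remove jitter effects by evaluating the closed form at actual times
        d = derive_trial(trial, cfg, seed=1)
        spi = d.spi(48)
        sched = trial.pain[trial.pain["context"] == "scheduled"]
        for sid, grp in sched.groupby("subject_id"):
            arm = trial.roster.set_index("subject_id").loc[sid, "arm"]
            traj = cfg.effect_model[arm]
            t = grp["time_h"].to_numpy()
            v = np.clip(np.floor(traj.mean(t) + 0.5), 0, 10)
            expected = compute_auc(t, v, 48)
            assert spi[sid] == pytest.approx(expected, rel=1e-9)

    def test_without_events_derived_spi_equals_raw_observed_spi(self):
        cfg = TrialConfig(
            n_per_arm=10, n_sites=2, rescue_hazard_base=0.0, dropout_rates={},
            missing_hour0_prob=0.0, sporadic_missing_prob=0.0,
        )
        trial = simulate_trial(cfg, seed=21)
        assert trial.rescue.empty and trial.events.empty
        d = derive_trial(trial, cfg, seed=21)
        spi = d.spi(48)
        sched = trial.pain[trial.pain["context"] == "scheduled"]
        for sid, grp in sched.groupby("subject_id"):
            raw = compute_auc(grp["time_h"], grp["score"], 48)
            assert spi[sid] == pytest.approx(raw, rel=1e-9)
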