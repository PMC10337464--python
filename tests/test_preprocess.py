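"""Weekly assembly: day aggregation, unmelting, adherence rules, imputation."""

import numpy as np
import pandas as pd
import pytest

from actistate.preprocess import (
    aggregate_day,
    exclude_patients,
    flag_dropped_weeks,
    impute_missing,
    preprocess_daily,
    remelt_daily,
    slot_columns,
    unmelt_weekly,
)


def make_daily(records, features=("steps_total", "hr_min")):
    """Small daily table from (patient, week, day, {feature: value}) tuples."""
    rows = []
    for pid, wk, day, vals in records:
        row = {"patient_id": pid, "week_index": wk, "day_of_week": day}
        for f in features:
            row[f] = vals.get(f, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def full_week(pid, wk, value=100.0, features=("steps_total", "hr_min")):
    return [
        (pid, wk, d, {f: value for f in features}) for d in range(1, 8)
    ]


class TestAggregateDay:
    def test_sleep_episode_inside_one_interval(self):
        stream = pd.DataFrame(
            {
                "patient_id": ["P1"],
                "timestamp": [pd.Timestamp("2023-01-02 01:00")],
                "feature": ["sleep_total_mins"],
                "value": [60.0],
                "duration_mins": [60.0],
            }
        )
        out = aggregate_day(stream)
        assert len(out) == 1
        assert out.iloc[0]["value"] == 60.0
        # 1 AM is inside the interval ending 8 PM on Jan 2
        assert out.iloc[0]["day"] == pd.Timestamp("2023-01-02")

    def test_heart_rate_min_max(self):
        stream = pd.DataFrame(
            {
                "patient_id": ["P1"] * 6,
                "timestamp": [pd.Timestamp("2023-01-02 10:00")] * 6,
                "feature": ["hr_min"] * 3 + ["hr_max"] * 3,
                "value": [60.0, 80.0, 75.0] * 2,
            }
        )
        out = aggregate_day(stream).set_index("feature")["value"]
        assert out["hr_min"] == 60.0 and out["hr_max"] == 80.0

    def test_boundary_spanning_episode_split_conserves_total(self):
        # 100 minutes of activity from 19:10 to 20:50: 50 before the 8 PM
        # boundary, 50 after, landing on adjacent daily records
        stream = pd.DataFrame(
            {
                "patient_id": ["P1"],
                "timestamp": [pd.Timestamp("2023-01-02 19:10")],
                "feature": ["activity_total_mins"],
                "value": [100.0],
                "duration_mins": [100.0],
            }
        )
        out = aggregate_day(stream)
        assert len(out) == 2
        assert out["value"].sum() == pytest.approx(100.0)
        assert sorted(out["value"]) == pytest.approx([50.0, 50.0])
        assert set(out["day"]) == {
            pd.Timestamp("2023-01-02"),
            pd.Timestamp("2023-01-03"),
        }

    def test_empty_stream(self):
        assert aggregate_day(pd.DataFrame(columns=["patient_id", "timestamp", "feature", "value"])).empty


class TestUnmelt:
    def test_complete_week_has_no_missing_slots(self):
        wk = unmelt_weekly(make_daily(full_week("P1", 1)))
        assert wk.data[wk.slots].notna().all().all()
        assert len(wk.data) == 1

    def test_slot_ordering_is_feature_major_day_ordered(self):
        recs = [("P1", 1, d, {"steps_total": float(d), "hr_min": 60.0}) for d in range(1, 8)]
        wk = unmelt_weekly(make_daily(recs))
        got = [wk.data.iloc[0][f"steps_total_d{d}"] for d in range(1, 8)]
        assert got == [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]
        assert wk.slots[:7] == [f"steps_total_d{d}" for d in range(1, 8)]

    def test_absent_days_become_missing_slots(self):
        recs = [r for r in full_week("P1", 1) if r[2] not in (3, 6)]
        wk = unmelt_weekly(make_daily(recs))
        assert int(wk.data[wk.slots].isna().sum(axis=1).iloc[0]) == 2 * 2  # 2 days x 2 features

    def test_duplicate_day_is_hard_error(self):
        recs = full_week("P1", 1) + [("P1", 1, 4, {"steps_total": 1.0})]
        with pytest.raises(ValueError, match="duplicate"):
            unmelt_weekly(make_daily(recs))


class TestDropAndExclude:
    def _cohort_with_missing(self, missing_days_by_week):
        """One patient; dict week -> set of missing days (all features)."""
        recs = []
        for wk, missing in missing_days_by_week.items():
            for d in range(1, 8):
                vals = {} if d in missing else {"steps_total": 1.0, "hr_min": 60.0}
                recs.append(("P1", wk, d, vals))
        return unmelt_weekly(make_daily(recs))

    def test_two_missing_days_not_dropped(self):
        wk = flag_dropped_weeks(self._cohort_with_missing({1: {2, 5}}))
        assert not wk.data["dropped"].any()

    def test_three_missing_days_one_feature_dropped(self):
        recs = full_week("P1", 1)
        df = make_daily(recs)
        df.loc[df["day_of_week"].isin([1, 2, 3]), "hr_min"] = np.nan  # steps intact
        wk = flag_dropped_weeks(unmelt_weekly(df))
        assert wk.data["dropped"].all()

    def test_flag_matches_brute_force_recount(self, rng):
        # randomized 100-week fixture with per-day joint missingness
        recs = []
        for p in range(10):
            for w in range(1, 11):
                for d in range(1, 8):
                    vals = (
                        {}
                        if rng.random() < 0.25
                        else {"steps_total": float(rng.random()), "hr_min": 60.0}
                    )
                    recs.append((f"P{p}", w, d, vals))
        daily = make_daily(recs)
        wk = flag_dropped_weeks(unmelt_weekly(daily))
        for _, row in wk.data.iterrows():
            n_missing = {
                f: sum(
                    pd.isna(row[f"{f}_d{d}"]) for d in range(1, 8)
                )
                for f in ("steps_total", "hr_min")
            }
            assert row["dropped"] == any(v >= 3 for v in n_missing.values())

    def test_patient_with_two_dropped_weeks_retained(self):
        wk = self._cohort_with_missing(
            {1: {1, 2, 3}, 2: {1, 2, 3}, 3: set(), 4: set()}
        )
        wk = exclude_patients(flag_dropped_weeks(wk))
        assert wk.data["patient_id"].nunique() == 1
        assert wk.data["dropped"].sum() == 2

    def test_patient_with_three_dropped_weeks_excluded(self):
        wk = self._cohort_with_missing(
            {1: {1, 2, 3}, 2: {1, 2, 3}, 3: {4, 5, 6}, 4: set()}
        )
        wk = exclude_patients(flag_dropped_weeks(wk))
        assert wk.data.empty

    def test_exclusion_matches_brute_force_on_synthetic(self, small_cohort):
        wk = flag_dropped_weeks(unmelt_weekly(small_cohort.daily))
        survivors = set(exclude_patients(wk).data["patient_id"])
        drops = wk.data.groupby("patient_id")["dropped"].sum()
        expect = {p for p, n in drops.items() if n < 3}
        assert survivors == expect


class TestImputation:
    def test_constant_previous_week_mean(self):
        recs = full_week("P1", 1, value=1000.0) + [
            r for r in full_week("P1", 2, value=2000.0) if r[2] != 3
        ]
        wk = impute_missing(flag_dropped_weeks(unmelt_weekly(make_daily(recs))))
        row2 = wk.data[wk.data["week_index"] == 2].iloc[0]
        assert row2["steps_total_d3"] == 1000.0
        assert wk.imputed.loc[row2.name, "steps_total_d3"]

    def test_first_week_falls_back_to_patient_mean(self):
        recs = [r for r in full_week("P1", 1, value=500.0) if r[2] != 2] + full_week(
            "P1", 2, value=900.0
        )
        wk = impute_missing(flag_dropped_weeks(unmelt_weekly(make_daily(recs))))
        row1 = wk.data[wk.data["week_index"] == 1].iloc[0]
        # patient observed 6 days at 500 (week 1) and 7 at 900 (week 2)
        expect = (6 * 500.0 + 7 * 900.0) / 13
        assert row1["steps_total_d2"] == pytest.approx(expect)

    def test_fully_observed_cohort_identity(self, clean_cohort):
        wk = flag_dropped_weeks(unmelt_weekly(clean_cohort.daily))
        out = impute_missing(wk)
        pd.testing.assert_frame_equal(out.data, wk.data.sort_values(
            ["patient_id", "week_index"]).reset_index(drop=True))
        assert not out.imputed.any().any()

    def test_idempotent(self, small_cohort):
        wk = exclude_patients(flag_dropped_weeks(unmelt_weekly(small_cohort.daily)))
        once = impute_missing(wk)
        twice = impute_missing(once)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_drop_flags_unchanged_by_imputation(self, small_cohort):
        wk = exclude_patients(flag_dropped_weeks(unmelt_weekly(small_cohort.daily)))
        before = wk.data.sort_values(["patient_id", "week_index"])["dropped"].tolist()
        after = impute_missing(wk).data["dropped"].tolist()
        assert before == after


class TestRoundTripAndPipeline:
    def test_remelt_conserves_complete_data(self, clean_cohort):
        wk = unmelt_weekly(clean_cohort.daily)
        back = remelt_daily(wk)
        orig = clean_cohort.daily.sort_values(
            ["patient_id", "week_index", "day_of_week"]
        ).reset_index(drop=True)
        back = back.sort_values(
            ["patient_id", "week_index", "day_of_week"]
        ).reset_index(drop=True)
        for f in wk.features:
            assert np.allclose(orig[f], back[f])

    def test_pipeline_equivalence_with_brute_force(self, small_cohort):
        """Full pipeline vs a direct re-implementation on a <=20 patient
        sub-cohort: same survivors, same drop flags, same imputed values."""
        keep = sorted(small_cohort.daily["patient_id"].unique())[:20]
        daily = small_cohort.daily[small_cohort.daily["patient_id"].isin(keep)]
        wk = preprocess_daily(daily)

        features = wk.features
        # brute force, dict-based
        cells = {}
        for _, r in daily.iterrows():
            for f in features:
                cells[(r["patient_id"], r["week_index"], r["day_of_week"], f)] = r[f]
        weeks = sorted({(p, w) for (p, w, _, _) in cells})

        def n_missing(p, w, f):
            return sum(
                1
                for d in range(1, 8)
                if pd.isna(cells.get((p, w, d, f), np.nan))
            )

        dropped = {
            (p, w): any(n_missing(p, w, f) >= 3 for f in features) for p, w in weeks
        }
        drops_per_patient = {}
        for (p, w), v in dropped.items():
            drops_per_patient[p] = drops_per_patient.get(p, 0) + int(v)
        survivors = {p for p, n in drops_per_patient.items() if n < 3}

        assert set(wk.data["patient_id"]) == survivors
        for _, row in wk.data.iterrows():
            assert row["dropped"] == dropped[(row["patient_id"], row["week_index"])]

        # imputation: previous-week mean, then patient mean
        for _, row in wk.data.iterrows():
            p, w = row["patient_id"], row["week_index"]
            if row["dropped"]:
                continue
            for f in features:
                for d in range(1, 8):
                    raw = cells.get((p, w, d, f), np.nan)
                    if not pd.isna(raw):
                        assert row[f"{f}_d{d}"] == raw
                        continue
                    prev = [
                        cells.get((p, w - 1, dd, f), np.nan) for dd in range(1, 8)
                    ]
                    prev = [v for v in prev if not pd.isna(v)]
                    if prev:
                        expect = np.mean(prev)
                    else:
                        mine = [
                            v
                            for (pp, ww, dd, ff), v in cells.items()
                            if pp == p and ff == f and not pd.isna(v)
                        ]
                        expect = np.mean(mine)
                    assert row[f"{f}_d{d}"] == pytest.approx(expect)


def test_slot_columns_are_105_for_full_feature_set(small_cohort):
    from actistate.synthetic import FEATURE_NAMES

    assert len(slot_columns(FEATURE_NAMES)) == 105
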