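"""Daily wear derivation and period summaries, checked against brute-force
oracles and the printed worked example (25 consecutive vs alternating days)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppdwear import wear

D = pd.Timestamp


def hour_rows(pairs, date="2020-01-01", person="p1"):
    return pd.DataFrame(
        [{"person_id": person, "date": D(date), "hour": h, "steps": s}
         for h, s in pairs]
    )


class TestHoursWornInDay:
    def test_no_rows_zero(self):
        assert wear.hours_worn_in_day(hour_rows([])) == 0

    def test_full_day(self):
        assert wear.hours_worn_in_day(
            hour_rows([(h, 1) for h in range(24)])
        ) == 24

    def test_zero_step_hours_do_not_count(self):
        rows = hour_rows([(7, 10), (8, 0), (12, 3), (19, 1)])
        assert wear.hours_worn_in_day(rows) == 3

    def test_duplicate_hour_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            wear.hours_worn_in_day(hour_rows([(7, 1), (7, 2)]))

    def test_negative_steps_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            wear.hours_worn_in_day(hour_rows([(7, -1)]))

    def test_matches_counting_oracle_on_random_tables(self, rng):
        for _ in range(1000):
            n = int(rng.integers(0, 25))
            hours = rng.choice(24, size=n, replace=False)
            steps = rng.integers(0, 4, size=n)
            rows = hour_rows(list(zip(hours, steps)))
            oracle = sum(1 for s in steps if s >= 1)
            assert wear.hours_worn_in_day(rows) == oracle


@pytest.mark.parametrize(
    "hours,steps,lenient,strict",
    [
        (0, 0, False, False),
        (1, 12, True, False),        # lenient threshold: at least 1 hour
        (10, 101, True, True),       # >=10 h and >100 steps: boundary in
        (9, 5000, True, False),      # 9 h fails the 10-hour floor
        (12, 100, True, False),      # 100 steps fails the strict > bound
        (12, 45000, True, False),    # 45000 fails the strict < bound
        (24, 44999, True, True),
    ],
)
def test_classify_day_boundaries(hours, steps, lenient, strict):
    assert wear.classify_day(hours, steps) == (lenient, strict)


class TestSleptWithDevice:
    def _rows(self, flags):
        return pd.DataFrame({
            "person_id": "p1", "sleep_date": D("2020-01-01"),
            "is_main_sleep": flags,
        })

    def test_no_rows_false(self):
        assert wear.slept_with_device(self._rows([])) is False

    def test_main_sleep_true(self):
        assert wear.slept_with_device(self._rows([True])) is True

    def test_only_non_main_sleep_false(self):
        assert wear.slept_with_device(self._rows([False, False])) is False


def brute_force_longest_run(flags):
    best = 0
    for i in range(len(flags)):
        for j in range(i, len(flags)):
            if all(flags[i:j + 1]):
                best = max(best, j - i + 1)
    return best


class TestMaxConsecutiveWorn:
    def test_all_false(self):
        assert wear.max_consecutive_worn([False] * 10) == 0

    def test_block_then_gap(self):
        assert wear.max_consecutive_worn([True] * 25 + [False] * 25) == 25

    def test_empty(self):
        assert wear.max_consecutive_worn([]) == 0

    @settings(max_examples=300, derandomize=True)
    @given(st.lists(st.booleans(), max_size=120))
    def test_matches_bruteforce_scan(self, flags):
        assert wear.max_consecutive_worn(flags) == brute_force_longest_run(flags)


def steps_for_worn_days(worn_dates, hours_per_day=16, person="p1"):
    rows = []
    for d in worn_dates:
        for h in range(hours_per_day):
            rows.append({"person_id": person, "date": D(d), "hour": h,
                         "steps": 100})
    return pd.DataFrame(rows,
                        columns=["person_id", "date", "hour", "steps"])


EMPTY_SLEEP = pd.DataFrame(columns=["person_id", "sleep_date", "is_main_sleep"])


class TestSummarizePeriod:
    def _summary(self, worn_dates, start="2020-01-01", n_days=50):
        steps = steps_for_worn_days(worn_dates)
        daily = wear.daily_wear(steps, EMPTY_SLEEP)
        end = D(start) + pd.Timedelta(days=n_days)
        res = wear.summarize_period("p1", "ppd", D(start), end, daily)
        assert res is not None
        return res

    def test_consecutive_block_fifty_percent(self):
        dates = pd.date_range("2020-01-01", periods=25, freq="D")
        summary, _ = self._summary(dates)
        assert summary["pct_worn"] == 50.0
        assert summary["max_consecutive_worn"] == 25
        assert summary["n_days_total"] == 50

    def test_alternating_fifty_percent(self):
        dates = pd.date_range("2020-01-01", periods=50, freq="D")[::2]
        summary, _ = self._summary(dates)
        assert summary["pct_worn"] == 50.0
        assert summary["max_consecutive_worn"] == 1

    def test_all_days_worn_sixteen_hours(self):
        dates = pd.date_range("2020-01-01", periods=50, freq="D")
        summary, hours_long = self._summary(dates)
        assert summary["pct_worn"] == 100.0
        assert summary["mean_hours_on_worn_days"] == 16.0
        assert (hours_long["hours_worn"] == 16).all()
        assert len(hours_long) == 50

    def test_empty_window_no_summary(self):
        daily = wear.daily_wear(steps_for_worn_days([]), EMPTY_SLEEP)
        assert wear.summarize_period(
            "p1", "ppd", D("2020-01-01"), D("2020-01-01"), daily
        ) is None


class TestDailyWearTable:
    def _random_inputs(self, rng, n_persons=4, n_days=30):
        rows = []
        for p in range(n_persons):
            for d in range(n_days):
                for h in sorted(rng.choice(24, rng.integers(0, 8),
                                           replace=False)):
                    rows.append({
                        "person_id": f"p{p}",
                        "date": D("2020-01-01") + pd.Timedelta(days=int(d)),
                        "hour": int(h),
                        "steps": int(rng.integers(0, 300)),
                    })
        steps = pd.DataFrame(rows)
        sleep = steps[["person_id", "date"]].drop_duplicates().sample(
            frac=0.5, random_state=0
        ).rename(columns={"date": "sleep_date"}).assign(is_main_sleep=True)
        return steps, sleep

    def test_strict_implies_lenient(self, rng):
        steps, sleep = self._random_inputs(rng)
        daily = wear.daily_wear(steps, sleep)
        assert (~daily["worn_strict"] | daily["worn_lenient"]).all()
        assert ((daily["total_steps"] == 0) <= (daily["hours_worn"] == 0)).all()

    def test_row_order_invariance(self, rng):
        steps, sleep = self._random_inputs(rng)
        shuffled = steps.sample(frac=1.0, random_state=1).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            wear.daily_wear(steps, sleep), wear.daily_wear(shuffled, sleep)
        )

    def test_duplicate_person_date_hour_rejected(self):
        steps = steps_for_worn_days(["2020-01-01"])
        dup = pd.concat([steps, steps.iloc[:1]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            wear.daily_wear(dup, EMPTY_SLEEP)


def test_strict_pct_never_exceeds_lenient_on_synthetic(small_bundle,
                                                       small_cohort):
    _, windows = small_cohort
    daily = wear.daily_wear(small_bundle.steps, small_bundle.sleep)
    summaries, _ = wear.summarize(daily, windows)
    assert (summaries["pct_worn_strict"] <= summaries["pct_worn"] + 1e-12).all()
    assert summaries["pct_worn"].between(0, 100).all()
    assert (
        summaries["max_consecutive_worn"] <= summaries["n_days_worn"]
    ).all()
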