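"""Daily wear facts from hourly steps and sleep, and per-period summaries.

Wear is inferred from the presence of step data: an hour is a worn hour iff
its step count is at least 1, a day is worn (lenient rule) iff it has at
least one worn hour, and a day is a valid worn day under the strict
sensitivity rule iff it has >=10 worn hours and a daily step total strictly
between 100 and 45,000.  A day is "worn to sleep" iff it carries a main-sleep
record.  Percent-worn denominators count every calendar day of the (clipped)
period window, so in-window days with no data at all are unworn days.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .constants import (
    STRICT_MAX_STEPS,
    STRICT_MIN_HOURS,
    STRICT_MIN_STEPS,
)

DAILY_COLUMNS = [
    "person_id", "date", "hours_worn", "total_steps",
    "worn_lenient", "worn_strict", "slept_with_device",
]

SUMMARY_COLUMNS = [
    "person_id", "period", "n_days_total", "n_days_worn", "pct_worn",
    "n_days_worn_strict", "pct_worn_strict", "n_days_sleep", "pct_sleep",
    "max_consecutive_worn", "mean_hours_on_worn_days",
]


def _validate_steps(steps: pd.DataFrame) -> None:
    if (steps["steps"] < 0).any():
        raise ValueError("negative step counts in hourly step table")
    if ((steps["hour"] < 0) | (steps["hour"] > 23)).any():
        raise ValueError("hour values outside 0-23 in hourly step table")
    if steps.duplicated(["person_id", "date", "hour"]).any():
        dup = steps[steps.duplicated(["person_id", "date", "hour"])].iloc[0]
        raise ValueError(
            f"duplicate hourly row for person {dup['person_id']} on "
            f"{pd.Timestamp(dup['date']).date()} hour {int(dup['hour'])}"
        )


def hours_worn_in_day(hour_rows: pd.DataFrame) -> int:
    """Count of distinct hours with steps >= 1 for one person-date."""
    if hour_rows.empty:
        return 0
    if (hour_rows["steps"] < 0).any():
        raise ValueError("negative step counts")
    if ((hour_rows["hour"] < 0) | (hour_rows["hour"] > 23)).any():
        raise ValueError("hour values outside 0-23")
    if hour_rows["hour"].duplicated().any():
        raise ValueError("duplicate hour rows for a single day")
    return int((hour_rows["steps"] >= 1).sum())


def classify_day(hours_worn: int, total_steps: int) -> tuple[bool, bool]:
    """(worn_lenient, worn_strict) for one day."""
    lenient = hours_worn >= 1
    strict = (
        hours_worn >= STRICT_MIN_HOURS
        and STRICT_MIN_STEPS < total_steps < STRICT_MAX_STEPS
    )
    return lenient, strict


def slept_with_device(sleep_rows: pd.DataFrame) -> bool:
    """True iff the person-date has at least one main-sleep record."""
    if sleep_rows.empty:
        return False
    return bool(sleep_rows["is_main_sleep"].astype(bool).any())


def daily_wear(steps: pd.DataFrame, sleep: pd.DataFrame) -> pd.DataFrame:
    """DailyWear facts for every person-date appearing in either input."""
    _validate_steps(steps)
    worn = steps[steps["steps"] >= 1]
    by_day = (
        worn.groupby(["person_id", "date"], sort=True)
        .agg(hours_worn=("hour", "nunique"), total_steps=("steps", "sum"))
        .reset_index()
    )
    # days whose only rows carry zero steps still exist, with zero worn hours
    zero_days = (
        steps.loc[~steps.set_index(["person_id", "date"]).index.isin(
            by_day.set_index(["person_id", "date"]).index
        ), ["person_id", "date"]]
        .drop_duplicates()
    )
    if not zero_days.empty:
        zero_days = zero_days.assign(hours_worn=0, total_steps=0)
        by_day = pd.concat([by_day, zero_days], ignore_index=True)

    main_sleep = sleep[sleep["is_main_sleep"].astype(bool)]
    slept = (
        main_sleep[["person_id", "sleep_date"]]
        .drop_duplicates()
        .rename(columns={"sleep_date": "date"})
        .assign(slept_with_device=True)
    )
    out = by_day.merge(slept, on=["person_id", "date"], how="outer")
    out["hours_worn"] = out["hours_worn"].fillna(0).astype(int)
    out["total_steps"] = out["total_steps"].fillna(0).astype(int)
    out["slept_with_device"] = out["slept_with_device"].eq(True)
    out["worn_lenient"] = out["hours_worn"] >= 1
    out["worn_strict"] = (
        (out["hours_worn"] >= STRICT_MIN_HOURS)
        & (out["total_steps"] > STRICT_MIN_STEPS)
        & (out["total_steps"] < STRICT_MAX_STEPS)
    )
    return (
        out.sort_values(["person_id", "date"])
        .reset_index(drop=True)[DAILY_COLUMNS]
    )


def max_consecutive_worn(worn_flags) -> int:
    """Length of the longest run of consecutive worn days."""
    flags = np.asarray(worn_flags, dtype=bool)
    if flags.size == 0:
        return 0
    padded = np.concatenate(([False], flags, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    if starts.size == 0:
        return 0
    return int((ends - starts).max())


def summarize_period(
    person_id, period, window_start, window_end, daily: pd.DataFrame
) -> tuple[dict, pd.DataFrame] | None:
    """PeriodSummary for one clipped window, or ``None`` if it is empty.

    ``daily`` holds the person's DailyWear rows.  Every calendar day of the
    window enters the denominator; days without rows count as unworn.
    Returns the summary row plus the long worn-day hours table used by the
    daily-hours mixed model (worn days only).
    """
    window_start = pd.Timestamp(window_start)
    window_end = pd.Timestamp(window_end)
    n_days = (window_end - window_start).days
    if n_days <= 0:
        return None
    calendar = pd.DataFrame(
        {"date": pd.date_range(window_start, periods=n_days, freq="D")}
    )
    d = calendar.merge(
        daily[daily["person_id"] == person_id], on="date", how="left"
    )
    for col in ("hours_worn", "total_steps"):
        d[col] = d[col].fillna(0)
    for col in ("worn_lenient", "worn_strict", "slept_with_device"):
        d[col] = d[col].eq(True)
    worn = d["worn_lenient"].to_numpy()
    n_worn = int(worn.sum())
    n_strict = int(d["worn_strict"].astype(bool).sum())
    n_sleep = int(d["slept_with_device"].astype(bool).sum())
    worn_days = d[worn]
    summary = {
        "person_id": person_id,
        "period": period,
        "n_days_total": n_days,
        "n_days_worn": n_worn,
        "pct_worn": 100.0 * n_worn / n_days,
        "n_days_worn_strict": n_strict,
        "pct_worn_strict": 100.0 * n_strict / n_days,
        "n_days_sleep": n_sleep,
        "pct_sleep": 100.0 * n_sleep / n_days,
        "max_consecutive_worn": max_consecutive_worn(worn),
        "mean_hours_on_worn_days": (
            float(worn_days["hours_worn"].mean()) if n_worn else np.nan
        ),
    }
    hours_long = pd.DataFrame(
        {
            "person_id": person_id,
            "date": worn_days["date"].to_numpy(),
            "period": period,
            "hours_worn": worn_days["hours_worn"].astype(int).to_numpy(),
        }
    )
    return summary, hours_long


def summarize(
    daily: pd.DataFrame, windows: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per person-period summaries over clipped windows.

    Returns (period_summary, worn_day_hours); empty windows emit no row.
    """
    summaries, hours_parts = [], []
    daily_by_person = dict(tuple(daily.groupby("person_id")))
    empty = daily.iloc[0:0]
    for row in windows.itertuples(index=False):
        person_daily = daily_by_person.get(row.person_id, empty)
        res = summarize_period(
            row.person_id, row.period, row.start_date, row.end_date, person_daily
        )
        if res is None:
            continue
        summary, hours_long = res
        summaries.append(summary)
        if not hours_long.empty:
            hours_parts.append(hours_long)
    period_summary = pd.DataFrame(summaries, columns=SUMMARY_COLUMNS)
    worn_day_hours = (
        pd.concat(hours_parts, ignore_index=True)
        if hours_parts
        else pd.DataFrame(columns=["person_id", "date", "period", "hours_worn"])
    )
    return period_summary, worn_day_hours
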