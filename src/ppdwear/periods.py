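"""Per-person pregnancy-period windows and day-to-period assignment.

Each person gets four half-open date windows ``[start, end)`` in fixed
chronological order: prepregnancy, pregnancy, postpartum, and PPD (or
PPD-equivalent for the non-PPD cohort).  Inclusive endpoints in the window
definitions ("30 days after the index date") are folded in as ``+ 1 day`` so
every boundary is half-open and unambiguous.

Window anchors
--------------
* PPD cohort: the PPD window spans 14 days before through 30 days after the
  index date (the earliest qualifying diagnosis/drug event); the postpartum
  window runs from delivery up to the start of the PPD window.
* Non-PPD cohort: the PPD-equivalent window starts at the index date
  (delivery + 58 days) with no 14-day lead, since these persons did not
  experience depression symptoms; postpartum runs from delivery to the index.
* Both cohorts: pregnancy spans ``[pregnancy_start, delivery)``, prepregnancy
  ``[index - 730 d, pregnancy_start)``.

Windows are made mutually disjoint by raising each window start to the
previous boundary; a window whose start meets its end is empty and a person
day can therefore fall in at most one period.
"""

from __future__ import annotations

import pandas as pd

from .constants import (
    COHORTS,
    DAYS_LOOKBACK,
    NONPPD,
    PERIODS,
    PPD,
    PPD_WINDOW_POST_DAYS,
    PPD_WINDOW_PRE_DAYS,
)

_DAY = pd.Timedelta(days=1)

WINDOW_COLUMNS = ["person_id", "period", "start_date", "end_date"]


def compute_windows_for_person(
    person_id,
    cohort: str,
    pregnancy_start_date,
    delivery_date,
    index_date,
) -> pd.DataFrame:
    """Four PeriodWindow rows for one person.

    Raises
    ------
    ValueError
        If the anchor dates violate ``pregnancy_start < delivery <= index``
        or the cohort label is unknown.
    """
    preg_start = pd.Timestamp(pregnancy_start_date)
    delivery = pd.Timestamp(delivery_date)
    index = pd.Timestamp(index_date)
    if cohort not in COHORTS:
        raise ValueError(f"unknown cohort {cohort!r}")
    if not (preg_start < delivery <= index):
        raise ValueError(
            f"person {person_id}: anchors must satisfy pregnancy_start < "
            f"delivery <= index (got {preg_start.date()}, {delivery.date()}, "
            f"{index.date()})"
        )

    if cohort == PPD:
        ppd_start = index - PPD_WINDOW_PRE_DAYS * _DAY
    else:
        ppd_start = index
    ppd_end = index + (PPD_WINDOW_POST_DAYS + 1) * _DAY

    # Nominal boundaries in chronological order; cummax keeps windows
    # disjoint when an early index pulls the PPD window before delivery.
    bounds = [
        index - DAYS_LOOKBACK * _DAY,  # prepregnancy start
        preg_start,                    # pregnancy start
        delivery,                      # postpartum start
        ppd_start,                     # ppd start
        ppd_end,                       # ppd end
    ]
    for i in range(1, len(bounds)):
        if bounds[i] < bounds[i - 1]:
            bounds[i] = bounds[i - 1]

    rows = []
    for period, start, end in zip(PERIODS, bounds[:-1], bounds[1:]):
        rows.append((person_id, period, start, end))
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


def compute_windows(assignments: pd.DataFrame) -> pd.DataFrame:
    """Windows for every person in a cohort-assignment table."""
    frames = [
        compute_windows_for_person(
            row.person_id,
            row.cohort,
            row.pregnancy_start_date,
            row.delivery_date,
            row.index_date,
        )
        for row in assignments.itertuples(index=False)
    ]
    if not frames:
        return pd.DataFrame(columns=WINDOW_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def clip_to_first_wear(windows: pd.DataFrame, first_step_dates) -> pd.DataFrame:
    """Raise window starts to the person's first recorded step date.

    ``first_step_dates`` maps person_id -> first date with any step row
    (a dict or Series).  Persons absent from the mapping own no device at
    any point: all their windows are emptied.  Days before the first
    recorded date never enter a denominator, so nobody is counted as not
    wearing a device they did not yet own.
    """
    out = windows.copy()
    first = out["person_id"].map(pd.Series(first_step_dates))
    # no step data at all -> empty every window
    no_data = first.isna()
    start = out["start_date"].where(~no_data, out["end_date"])
    first = pd.to_datetime(first)
    clipped = start.mask(~no_data & (first > start), first)
    out["start_date"] = clipped.mask(clipped > out["end_date"], out["end_date"])
    return out


def window_lengths(windows: pd.DataFrame) -> pd.Series:
    """Window length in days (half-open, so simply end - start)."""
    return (windows["end_date"] - windows["start_date"]).dt.days


def assign_day(person_id, date, windows: pd.DataFrame):
    """Period containing ``date`` for this person, or ``None``.

    Raises ``RuntimeError`` if the person's windows overlap (internal
    invariant violation).
    """
    date = pd.Timestamp(date)
    w = windows[windows["person_id"] == person_id]
    hits = w[(w["start_date"] <= date) & (date < w["end_date"])]
    if len(hits) > 1:
        raise RuntimeError(f"overlapping windows for person {person_id}")
    if hits.empty:
        return None
    return hits["period"].iloc[0]


def day_assignments(windows: pd.DataFrame) -> pd.DataFrame:
    """Long table (person_id, date, period) enumerating every in-window day."""
    parts = []
    for row in windows.itertuples(index=False):
        n = (row.end_date - row.start_date).days
        if n <= 0:
            continue
        dates = pd.date_range(row.start_date, periods=n, freq="D")
        parts.append(
            pd.DataFrame(
                {"person_id": row.person_id, "date": dates, "period": row.period}
            )
        )
    if not parts:
        return pd.DataFrame(columns=["person_id", "date", "period"])
    out = pd.concat(parts, ignore_index=True)
    dup = out.duplicated(["person_id", "date"])
    if dup.any():
        pid = out.loc[dup, "person_id"].iloc[0]
        raise RuntimeError(f"overlapping windows for person {pid}")
    return out
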