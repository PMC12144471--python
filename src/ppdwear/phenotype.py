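"""Computational phenotyping: PPD / non-PPD cohort assignment from EHR events.

A person belongs to the PPD cohort if, relative to her delivery date, she has
any of

1. a PPD diagnosis on or after delivery and within 730 days (24 months),
2. a depression diagnosis strictly after delivery and within 730 days, or
3. an antidepressant exposure strictly after delivery and within 730 days

(the depression/antidepressant rules use an exclusive lower bound because the
event must fall *during* the postpartum period, while a PPD diagnosis on the
delivery date itself counts).  Everyone else with a delivery is non-PPD.

The index date anchoring the fourth analysis period is the earliest
qualifying event for PPD persons and delivery + 58 days (the median
delivery-to-diagnosis delay) for non-PPD persons.
"""

from __future__ import annotations

import logging

import pandas as pd

from .constants import (
    DAYS_PREGNANCY_FALLBACK,
    DAYS_QUALIFYING_WINDOW,
    EV_ANTIDEPRESSANT,
    EV_DELIVERY,
    EV_DEPRESSION_DIAGNOSIS,
    EV_PPD_DIAGNOSIS,
    EV_PREGNANCY_START,
    EVENT_TYPES,
    NONPPD,
    NONPPD_INDEX_OFFSET_DAYS,
    PPD,
)

logger = logging.getLogger(__name__)

_DAY = pd.Timedelta(days=1)

ASSIGNMENT_COLUMNS = [
    "person_id", "cohort", "pregnancy_start_date", "delivery_date",
    "index_date", "age_at_index_years", "race_ethnicity", "income_level",
]


def validate_events(events: pd.DataFrame) -> None:
    """Schema check for a clinical-event table."""
    required = {"person_id", "event_type", "event_date"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"events table missing columns {sorted(missing)}")
    bad = set(events["event_type"].unique()) - set(EVENT_TYPES)
    if bad:
        raise ValueError(f"unknown event types {sorted(bad)}")
    if pd.to_datetime(events["event_date"]).isna().any():
        raise ValueError("events table contains unparseable event_date values")


def resolve_pregnancy_start(person_events: pd.DataFrame, delivery_date) -> pd.Timestamp:
    """Pregnancy start: earliest recorded pregnancy event before delivery,
    else delivery − 270 days (the standard 9-month pregnancy length)."""
    delivery = pd.Timestamp(delivery_date)
    preg = person_events[person_events["event_type"] == EV_PREGNANCY_START]
    valid = preg[pd.to_datetime(preg["event_date"]) < delivery]
    if not valid.empty:
        return pd.to_datetime(valid["event_date"]).min()
    if not preg.empty:
        pid = preg["person_id"].iloc[0]
        logger.warning(
            "person %s: pregnancy_start on/after delivery; falling back to "
            "delivery - %d days", pid, DAYS_PREGNANCY_FALLBACK,
        )
    return delivery - DAYS_PREGNANCY_FALLBACK * _DAY


def _qualifying_dates(person_events: pd.DataFrame, delivery: pd.Timestamp) -> pd.Series:
    """Dates of PPD-qualifying events within the 24-month postpartum window."""
    ev = person_events.copy()
    ev["event_date"] = pd.to_datetime(ev["event_date"])
    horizon = delivery + DAYS_QUALIFYING_WINDOW * _DAY
    is_ppd = (
        (ev["event_type"] == EV_PPD_DIAGNOSIS)
        & (ev["event_date"] >= delivery)
        & (ev["event_date"] <= horizon)
    )
    is_postpartum_dep = (
        ev["event_type"].isin([EV_DEPRESSION_DIAGNOSIS, EV_ANTIDEPRESSANT])
        & (ev["event_date"] > delivery)
        & (ev["event_date"] <= horizon)
    )
    return ev.loc[is_ppd | is_postpartum_dep, "event_date"]


def assign_cohort(person_events: pd.DataFrame, person_attrs: dict) -> dict | None:
    """CohortAssignment fields for one person, or ``None`` if no delivery.

    When a person has several deliveries the earliest one with a resolvable
    pregnancy start is used.
    """
    pid = person_attrs["person_id"]
    deliveries = person_events[person_events["event_type"] == EV_DELIVERY]
    if deliveries.empty:
        logger.info("person %s excluded: no delivery event", pid)
        return None
    delivery = pd.to_datetime(deliveries["event_date"]).min()

    qual = _qualifying_dates(person_events, delivery)
    if not qual.empty:
        cohort, index = PPD, qual.min()
    else:
        cohort, index = NONPPD, delivery + NONPPD_INDEX_OFFSET_DAYS * _DAY
        late = person_events["event_type"].isin(
            [EV_PPD_DIAGNOSIS, EV_DEPRESSION_DIAGNOSIS, EV_ANTIDEPRESSANT]
        )
        if late.any():
            logger.info(
                "person %s: depression evidence outside the 24-month window; "
                "labeled non-PPD", pid,
            )

    preg_start = resolve_pregnancy_start(person_events, delivery)
    age = person_attrs.get("age_at_index_years")
    return {
        "person_id": pid,
        "cohort": cohort,
        "pregnancy_start_date": preg_start,
        "delivery_date": delivery,
        "index_date": index,
        "age_at_index_years": age,
        "race_ethnicity": person_attrs.get("race_ethnicity"),
        "income_level": person_attrs.get("income_level"),
    }


def assign_cohorts(
    events: pd.DataFrame, persons: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign every person; returns (assignments, exclusions)."""
    validate_events(events)
    ev = events.copy()
    ev["event_date"] = pd.to_datetime(ev["event_date"])
    grouped = dict(tuple(ev.groupby("person_id")))
    rows, excluded = [], []
    for attrs in persons.to_dict("records"):
        pid = attrs["person_id"]
        pe = grouped.get(pid)
        if pe is None or pe[pe["event_type"] == EV_DELIVERY].empty:
            excluded.append({"person_id": pid, "reason": "no_delivery_event"})
            continue
        rows.append(assign_cohort(pe, attrs))
    assignments = pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)
    exclusions = pd.DataFrame(excluded, columns=["person_id", "reason"])
    return assignments, exclusions


def filter_eligible(
    assignments: pd.DataFrame,
    steps: pd.DataFrame,
    windows: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep persons with any step data inside the union of their windows.

    Returns (retained assignments, exclusions with reasons).
    """
    merged = steps[["person_id", "date"]].merge(windows, on="person_id")
    in_window = merged[
        (merged["date"] >= merged["start_date"])
        & (merged["date"] < merged["end_date"])
    ]
    eligible = set(in_window["person_id"].unique())
    keep = assignments["person_id"].isin(eligible)
    excluded = pd.DataFrame(
        {
            "person_id": assignments.loc[~keep, "person_id"],
            "reason": "no_wearable_data_in_any_period",
        },
        columns=["person_id", "reason"],
    )
    return assignments[keep].reset_index(drop=True), excluded.reset_index(drop=True)
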