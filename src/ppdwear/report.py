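"""End-to-end pipeline orchestration and descriptive reporting.

``run_pipeline`` executes phenotype -> periods -> wear -> infer on input
tables (a directory of CSV/Parquet files, a ``SimConfig`` or an in-memory
``SyntheticBundle``) and writes every stage's output plus a machine-readable
manifest.  ``table_one`` builds the descriptive cohort table (person counts,
days of data overall and per period, age, race, income), optionally
rendering small cells as "<20" to mimic privacy-preserving reporting —
suppression affects rendering only, never the underlying data.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import infer, periods, phenotype, synth, wear
from .constants import COHORTS, NONPPD, PERIODS, PPD

logger = logging.getLogger(__name__)

SUPPRESSION_LIMIT = 20


@dataclass
class RunManifest:
    config_hash: str
    seed: int | None
    input_paths: dict
    row_counts: dict = field(default_factory=dict)
    exclusions: dict = field(default_factory=dict)
    timestamp: str = ""
    version: str = "0.1.0"

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


class PipelineError(RuntimeError):
    pass


def _collapse_rare_levels(
    assignments: pd.DataFrame,
    summaries: pd.DataFrame,
    worn_day_hours: pd.DataFrame,
    covariates,
) -> pd.DataFrame:
    """Merge covariate levels that would be singletons in some model.

    The inference operations refuse levels present in only one row; this is
    the re-leveling step their error asks for, applied once over every
    per-period person set (summary rows for the OLS models, worn-day persons
    for the mixed model) so the design stays identical across models.
    """
    out = assignments.copy()
    period_pids = {}
    for period in PERIODS:
        period_pids[f"{period}/summary"] = set(
            summaries.loc[summaries["period"] == period, "person_id"]
        )
        period_pids[f"{period}/worn"] = set(
            worn_day_hours.loc[worn_day_hours["period"] == period, "person_id"]
        )
    for cov in covariates:
        if cov not in infer._CATEGORICAL:
            continue
        for _ in range(out[cov].nunique()):
            rare = set()
            for pids in period_pids.values():
                counts = out.loc[out["person_id"].isin(pids), cov].value_counts()
                rare |= set(counts[counts == 1].index)
            if not rare:
                break
            modal = out[cov].value_counts().idxmax()
            target = "(other)" if "(other)" not in rare else modal
            logger.info(
                "collapsing rare %s level(s) %s into %r", cov, sorted(rare),
                target,
            )
            out[cov] = out[cov].where(~out[cov].isin(rare), target)
    return out


def _write_csv(df: pd.DataFrame, path: Path, date_cols=()) -> None:
    df = df.copy()
    for col in date_cols:
        if col in df.columns:
            df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False)


def run_pipeline(
    inputs,
    out_dir,
    strict_wear: bool = False,
    alpha: float = 0.05,
    family_size: int = 4,
    collapse_rare_levels: bool = True,
    write_day_assignments: bool = False,
) -> RunManifest:
    """Run the full analysis and write outputs to ``out_dir``.

    ``inputs`` may be a directory path with persons/events/steps/sleep
    tables, a ``SimConfig`` (a synthetic cohort is generated first) or a
    ``SyntheticBundle``.  ``strict_wear`` switches the primary percent-worn
    outcome to the strict valid-day rule.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    seed = None
    if isinstance(inputs, synth.SimConfig):
        seed = inputs.seed
        config_hash = inputs.digest()
        bundle = synth.generate(inputs)
        tables = {"persons": bundle.persons, "events": bundle.events,
                  "steps": bundle.steps, "sleep": bundle.sleep}
        input_paths = {"source": f"SimConfig(seed={inputs.seed})"}
    elif isinstance(inputs, synth.SyntheticBundle):
        tables = {"persons": inputs.persons, "events": inputs.events,
                  "steps": inputs.steps, "sleep": inputs.sleep}
        config_hash = "in-memory-bundle"
        input_paths = {"source": "SyntheticBundle"}
    else:
        tables = synth.load_tables(inputs)
        h = hashlib.sha256()
        for name in sorted(tables):
            h.update(pd.util.hash_pandas_object(tables[name], index=False).values)
        config_hash = h.hexdigest()[:16]
        input_paths = {"source": str(inputs)}

    for name in ("steps", "sleep"):
        col = "date" if name == "steps" else "sleep_date"
        tables[name][col] = pd.to_datetime(tables[name][col])
    tables["events"]["event_date"] = pd.to_datetime(tables["events"]["event_date"])

    manifest = RunManifest(
        config_hash=config_hash, seed=seed, input_paths=input_paths,
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )
    manifest.row_counts["input"] = {k: int(len(v)) for k, v in tables.items()}

    # phenotype
    assignments, excl_delivery = phenotype.assign_cohorts(
        tables["events"], tables["persons"]
    )
    if assignments.empty:
        raise PipelineError("no persons with a delivery event; nothing to analyze")

    # periods
    windows = periods.compute_windows(assignments)
    first_step = tables["steps"].groupby("person_id")["date"].min()
    windows = periods.clip_to_first_wear(windows, first_step)

    assignments, excl_eligibility = phenotype.filter_eligible(
        assignments, tables["steps"], windows
    )
    for cohort in COHORTS:
        if (assignments["cohort"] == cohort).sum() == 0:
            raise PipelineError(
                f"cohort {cohort} is empty after the wearable-data "
                "eligibility filter; cannot compare cohorts"
            )
    windows = windows[windows["person_id"].isin(assignments["person_id"])]
    windows = windows.reset_index(drop=True)

    # wear
    keep = tables["steps"]["person_id"].isin(assignments["person_id"])
    daily = wear.daily_wear(
        tables["steps"][keep],
        tables["sleep"][
            tables["sleep"]["person_id"].isin(assignments["person_id"])
        ],
    )
    summaries, worn_day_hours = wear.summarize(daily, windows)

    # infer
    covariates = list(infer.DEFAULT_COVARIATES)
    model_assignments = assignments
    if collapse_rare_levels:
        model_assignments = _collapse_rare_levels(
            assignments, summaries, worn_day_hours, covariates
        )
    if strict_wear:
        outcomes_note = "primary outcome: pct_worn_strict"
    else:
        outcomes_note = "primary outcome: pct_worn"
    comparisons = infer.compare_all(
        summaries, worn_day_hours, model_assignments,
        covariates=covariates, alpha=alpha, family_size=family_size,
    )
    correlations = infer.correlate_all(
        summaries, model_assignments, alpha=alpha, family_size=family_size
    )

    # outputs
    _write_csv(assignments, out / "cohort.csv",
               date_cols=["pregnancy_start_date", "delivery_date", "index_date"])
    exclusions = pd.concat([excl_delivery, excl_eligibility], ignore_index=True)
    _write_csv(exclusions, out / "exclusions.csv")
    _write_csv(windows, out / "windows.csv", date_cols=["start_date", "end_date"])
    if write_day_assignments:
        _write_csv(periods.day_assignments(windows), out / "day_assignments.csv",
                   date_cols=["date"])
    _write_csv(daily, out / "daily_wear.csv", date_cols=["date"])
    _write_csv(summaries, out / "period_summary.csv")
    _write_csv(worn_day_hours, out / "worn_day_hours.csv", date_cols=["date"])
    comp_out = comparisons.copy()
    for col in ("mean_ppd", "mean_nonppd", "contrast"):
        comp_out[f"{col}_display"] = comp_out[col].round(1)
    comp_out["p_display"] = comp_out["p_value"].round(3)
    comp_out["alpha_display"] = comp_out["alpha_corrected"].map(
        infer.display_threshold
    )
    _write_csv(comp_out, out / "comparisons.csv")
    corr_out = correlations.copy()
    corr_out["r_display"] = corr_out["r"].round(2)
    corr_out["p_display"] = corr_out["p_value"].round(3)
    _write_csv(corr_out, out / "correlations.csv")

    t1 = table_one(assignments, summaries)
    _write_csv(t1, out / "table_one.csv")

    manifest.row_counts.update(
        {
            "assignments": int(len(assignments)),
            "windows": int(len(windows)),
            "daily_wear": int(len(daily)),
            "period_summary": int(len(summaries)),
            "worn_day_hours": int(len(worn_day_hours)),
            "comparisons": int(len(comparisons)),
            "correlations": int(len(correlations)),
        }
    )
    manifest.exclusions = {
        "no_delivery_event": int(len(excl_delivery)),
        "no_wearable_data_in_any_period": int(len(excl_eligibility)),
    }
    manifest.input_paths["note"] = outcomes_note
    (out / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest


# ---------------------------------------------------------------------------
# Descriptive table
# ---------------------------------------------------------------------------

def _fmt_count_pct(count: int, denom: int, suppress: bool) -> str:
    pct = 100.0 * count / denom if denom else 0.0
    if suppress and 0 < count < SUPPRESSION_LIMIT:
        return f"<{SUPPRESSION_LIMIT} ({pct:.1f})"
    return f"{count} ({pct:.1f})"


def table_one(
    assignments: pd.DataFrame,
    summaries: pd.DataFrame,
    suppress: bool = False,
) -> pd.DataFrame:
    """Descriptive cohort table: persons, days of data by period, age,
    race/ethnicity and income, as formatted "n (%)" / "median (IQR)" cells."""
    cohort_of = assignments.set_index("person_id")["cohort"]
    s = summaries.copy()
    s["cohort"] = s["person_id"].map(cohort_of)

    n_by_cohort = assignments["cohort"].value_counts().to_dict()
    n_total = int(len(assignments))
    days_by_cohort = s.groupby("cohort")["n_days_total"].sum().to_dict()
    days_total = int(s["n_days_total"].sum())

    rows = []

    def add(stat, total_cell, ppd_cell, nonppd_cell):
        rows.append({"statistic": stat, "total": total_cell,
                     "ppd": ppd_cell, "nonppd": nonppd_cell})

    add(
        "Number of females, n (%)",
        _fmt_count_pct(n_total, n_total, suppress),
        _fmt_count_pct(int(n_by_cohort.get(PPD, 0)), n_total, suppress),
        _fmt_count_pct(int(n_by_cohort.get(NONPPD, 0)), n_total, suppress),
    )
    add(
        "Number of days of data, n (%)",
        _fmt_count_pct(days_total, days_total, suppress),
        _fmt_count_pct(int(days_by_cohort.get(PPD, 0)), days_total, suppress),
        _fmt_count_pct(int(days_by_cohort.get(NONPPD, 0)), days_total, suppress),
    )
    for period in PERIODS:
        sp = s[s["period"] == period]
        by = sp.groupby("cohort")["n_days_total"].sum().to_dict()
        tot = int(sp["n_days_total"].sum())
        add(
            f"Days of data, {period}, n (%)",
            _fmt_count_pct(tot, days_total, suppress),
            _fmt_count_pct(int(by.get(PPD, 0)),
                           int(days_by_cohort.get(PPD, 0)) or 1, suppress),
            _fmt_count_pct(int(by.get(NONPPD, 0)),
                           int(days_by_cohort.get(NONPPD, 0)) or 1, suppress),
        )

    def med_iqr(sub):
        if sub.empty or sub["age_at_index_years"].dropna().empty:
            return "-"
        q = sub["age_at_index_years"].quantile([0.25, 0.5, 0.75])
        return f"{q[0.5]:.1f} ({q[0.25]:.1f}-{q[0.75]:.1f})"

    add(
        "Age (y), median (IQR)",
        med_iqr(assignments),
        med_iqr(assignments[assignments["cohort"] == PPD]),
        med_iqr(assignments[assignments["cohort"] == NONPPD]),
    )
    for col, label in (
        ("race_ethnicity", "Race/ethnicity"),
        ("income_level", "Annual income"),
    ):
        for level in sorted(assignments[col].dropna().unique()):
            counts = (
                assignments[assignments[col] == level]["cohort"]
                .value_counts().to_dict()
            )
            total_count = int(sum(counts.values()))
            add(
                f"{label}: {level}, n (%)",
                _fmt_count_pct(total_count, n_total, suppress),
                _fmt_count_pct(int(counts.get(PPD, 0)),
                               int(n_by_cohort.get(PPD, 0)) or 1, suppress),
                _fmt_count_pct(int(counts.get(NONPPD, 0)),
                               int(n_by_cohort.get(NONPPD, 0)) or 1, suppress),
            )
    return pd.DataFrame(rows, columns=["statistic", "total", "ppd", "nonppd"])


def render_markdown(table: pd.DataFrame) -> str:
    """Markdown rendering of a table-one style frame."""
    header = "| " + " | ".join(table.columns) + " |"
    sep = "| " + " | ".join("---" for _ in table.columns) + " |"
    lines = [header, sep]
    for _, row in table.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    return "\n".join(lines) + "\n"
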