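"""Synthetic EHR + wearable data with the structure the analysis assumes.

The real study population (pregnant females sharing Fitbit data under a
bring-your-own-device model, phenotyped for postpartum depression from EHR
events) is access-restricted, so this module generates tables with the same
schemas and the statistical features the downstream pipeline relies on:

* per-person pregnancy-start / delivery / PPD-qualifying events, with the
  delivery-to-diagnosis delay drawn lognormal around a configurable median;
* hour-resolution step streams whose *presence* encodes device wear — a worn
  day receives ``k`` distinct step-hours (``k`` normal, rounded, clipped to
  1-24) and an unworn day receives no rows;
* binary daily main-sleep records on a configurable fraction of worn days;
* cohort- and period-dependent daily worn probabilities with day-to-day
  persistence (a stationary two-state Markov chain) and a per-person
  logit-scale frailty that induces within-person cross-period correlation.

The frailty is additive on the logit scale; its location is adjusted per
(cohort, period) so the population mean worn probability equals the
configured ``wear_prob`` for any frailty sd (see docs/methods.md).

A ``truth`` table records each person's latent frailty and realized per-period
worn probability for parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from . import periods
from .constants import (
    COHORTS,
    EV_DELIVERY,
    EV_PREGNANCY_START,
    INCOME_LEVELS,
    NONPPD,
    NONPPD_INDEX_OFFSET_DAYS,
    PERIODS,
    PPD,
    PPD_QUALIFYING_EVENTS,
)


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


_DAY = pd.Timedelta(days=1)
_BASE_DATE = pd.Timestamp("2021-01-01")

# Default cohort x period daily worn probabilities, echoing the adjusted
# per-period wear percentages reported for the study cohorts.
DEFAULT_WEAR_PROB = {
    (PPD, "prepregnancy"): 0.475,
    (PPD, "pregnancy"): 0.468,
    (PPD, "postpartum"): 0.699,
    (PPD, "ppd"): 0.666,
    (NONPPD, "prepregnancy"): 0.486,
    (NONPPD, "pregnancy"): 0.405,
    (NONPPD, "postpartum"): 0.500,
    (NONPPD, "ppd"): 0.464,
}

DEFAULT_RACE_LEVELS = (
    "White_nonHispanic",
    "Black_nonHispanic",
    "Hispanic_or_Latinx",
    "Asian_nonHispanic",
    "Other",
)
DEFAULT_RACE_PROBS = (0.79, 0.07, 0.07, 0.04, 0.03)
DEFAULT_INCOME_PROBS = (0.03, 0.05, 0.05, 0.07, 0.12, 0.17, 0.25, 0.13, 0.08, 0.05)


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the study conditions: 41 PPD / 101 non-PPD persons,
    per-period worn probabilities at the reported adjusted means, 15-17
    worn hours per worn day, and a wide between-person spread in wear
    propensity (logit-scale frailty sd 2.5).
    """

    n_ppd: int = 41
    n_nonppd: int = 101
    wear_prob: dict = field(default_factory=lambda: dict(DEFAULT_WEAR_PROB))
    persistence_rho: float = 0.3
    hours_mu: float = 16.0
    hours_sd: float = 3.0
    hours_person_sd: float = 1.5
    sleep_given_worn: float = 0.85
    steps_per_worn_hour_mean: float = 400.0
    pregnancy_len_days: int = 270
    ppd_delay_median_days: float = 58.0
    ppd_delay_sigma: float = 0.6
    followup_pre_days: int = 730
    person_frailty_sd: float = 2.5
    age_range: tuple = (18.0, 45.0)
    race_levels: tuple = DEFAULT_RACE_LEVELS
    race_probs: tuple = DEFAULT_RACE_PROBS
    income_levels: tuple = INCOME_LEVELS
    income_probs: tuple = DEFAULT_INCOME_PROBS
    first_wear: str = "uniform"  # "uniform" | "window_start"
    seed: int = 0

    def __post_init__(self):
        self.wear_prob = {tuple(k) if not isinstance(k, str) else k: v
                          for k, v in self.wear_prob.items()}
        self.validate()

    def validate(self) -> None:
        if self.n_ppd < 0 or self.n_nonppd < 0:
            raise ConfigError("n_ppd/n_nonppd must be >= 0")
        for cohort in COHORTS:
            for period in PERIODS:
                key = (cohort, period)
                if key not in self.wear_prob:
                    raise ConfigError(f"wear_prob missing entry for {key}")
                p = self.wear_prob[key]
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"wear_prob[{key}] must be in [0,1], got {p}")
        if not 0.0 <= self.persistence_rho < 1.0:
            raise ConfigError(
                f"persistence_rho must be in [0,1), got {self.persistence_rho}"
            )
        if not 0.0 < self.hours_mu <= 24.0:
            raise ConfigError(f"hours_mu must be in (0,24], got {self.hours_mu}")
        if self.hours_sd < 0:
            raise ConfigError(f"hours_sd must be >= 0, got {self.hours_sd}")
        if self.hours_person_sd < 0:
            raise ConfigError(
                f"hours_person_sd must be >= 0, got {self.hours_person_sd}"
            )
        if not 0.0 <= self.sleep_given_worn <= 1.0:
            raise ConfigError(
                f"sleep_given_worn must be in [0,1], got {self.sleep_given_worn}"
            )
        if self.steps_per_worn_hour_mean <= 0:
            raise ConfigError("steps_per_worn_hour_mean must be > 0")
        if self.pregnancy_len_days <= 0:
            raise ConfigError("pregnancy_len_days must be > 0")
        if self.ppd_delay_median_days <= 0:
            raise ConfigError("ppd_delay_median_days must be > 0")
        if self.ppd_delay_sigma < 0:
            raise ConfigError("ppd_delay_sigma must be >= 0")
        if self.followup_pre_days < 0:
            raise ConfigError("followup_pre_days must be >= 0")
        if self.person_frailty_sd < 0:
            raise ConfigError("person_frailty_sd must be >= 0")
        if len(self.race_levels) != len(self.race_probs):
            raise ConfigError("race_levels and race_probs must have equal length")
        if len(self.income_levels) != len(self.income_probs):
            raise ConfigError("income_levels and income_probs must have equal length")
        for name, probs in (("race_probs", self.race_probs),
                            ("income_probs", self.income_probs)):
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-8:
                raise ConfigError(f"{name} must be non-negative and sum to 1")
        if self.first_wear not in ("uniform", "window_start"):
            raise ConfigError(
                f"first_wear must be 'uniform' or 'window_start', got {self.first_wear}"
            )

    _FIELDS = None  # filled below

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        """Build from a plain (YAML-loaded) mapping; unknown keys rejected.

        ``wear_prob`` may be nested ``{cohort: {period: p}}``.
        """
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        wp = d.get("wear_prob")
        if wp is not None and all(isinstance(v, dict) for v in wp.values()):
            d["wear_prob"] = {
                (cohort, period): p
                for cohort, by_period in wp.items()
                for period, p in by_period.items()
            }
        for key in ("age_range", "race_levels", "race_probs",
                    "income_levels", "income_probs"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["wear_prob"] = {f"{c}/{p}": v for (c, p), v in self.wear_prob.items()}
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_jsonable(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class SyntheticBundle:
    """Generated tables plus the latent truth used by recovery tests."""

    persons: pd.DataFrame
    events: pd.DataFrame
    steps: pd.DataFrame
    sleep: pd.DataFrame
    truth: pd.DataFrame

    _DATE_COLS = {
        "events": ["event_date"],
        "steps": ["date"],
        "sleep": ["sleep_date"],
        "truth": ["first_wear_date", "pregnancy_start_date", "delivery_date",
                  "index_date"],
    }

    def write(self, out_dir, fmt: str = "csv") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("persons", "events", "steps", "sleep", "truth"):
            df = getattr(self, name).copy()
            if fmt == "csv":
                for col in self._DATE_COLS.get(name, []):
                    df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
                df.to_csv(out / f"{name}.csv", index=False)
            elif fmt == "parquet":
                df.to_parquet(out / f"{name}.parquet", index=False)
            else:
                raise ValueError(f"unknown format {fmt!r}")


def load_tables(data_dir) -> dict:
    """Read persons/events/steps/sleep tables from CSV or Parquet."""
    data_dir = Path(data_dir)
    out = {}
    for name in ("persons", "events", "steps", "sleep"):
        csv, pq = data_dir / f"{name}.csv", data_dir / f"{name}.parquet"
        if pq.exists():
            df = pd.read_parquet(pq)
        elif csv.exists():
            df = pd.read_csv(csv)
        else:
            raise FileNotFoundError(f"missing input table {name} in {data_dir}")
        for col in SyntheticBundle._DATE_COLS.get(name, []):
            if col in df.columns:
                df[col] = pd.to_datetime(df[col])
        out[name] = df
    return out


# ---------------------------------------------------------------------------
# Wear-sequence mechanics
# ---------------------------------------------------------------------------

def simulate_wear_sequence(n_days: int, p: float, rho: float, rng) -> np.ndarray:
    """Worn/unworn flags from a stationary two-state Markov chain.

    The chain has stationary worn probability ``p`` and lag-1 correlation
    ``rho`` (``P(worn|worn) = p + rho(1-p)``, ``P(worn|unworn) = p(1-rho)``);
    the first state is drawn from the stationary law, so every day is
    marginally Bernoulli(p).
    """
    if n_days < 0:
        raise ValueError(f"n_days must be >= 0, got {n_days}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0,1], got {p}")
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must be in [0,1), got {rho}")
    flags = np.empty(n_days, dtype=bool)
    if n_days == 0:
        return flags
    u = rng.random(n_days)
    flags[0] = u[0] < p
    if rho == 0.0:
        flags[1:] = u[1:] < p
        return flags
    stay = p + rho * (1.0 - p)
    gain = p * (1.0 - rho)
    prev = flags[0]
    for t in range(1, n_days):
        prev = u[t] < (stay if prev else gain)
        flags[t] = prev
    return flags


def _draw_worn_hour_counts(n: int, hours_mu: float, hours_sd: float, rng) -> np.ndarray:
    k = np.rint(rng.normal(hours_mu, hours_sd, size=n)).astype(np.int64)
    return np.clip(k, 1, 24)


def _choose_distinct_hours(k: np.ndarray, rng):
    """For each count k_i, pick k_i distinct hours of the day (sorted)."""
    n = len(k)
    if n == 0:
        return np.repeat(np.arange(0), 0), np.empty(0, dtype=np.int64)
    perm = np.argsort(rng.random((n, 24)), axis=1)
    mask = np.arange(24)[None, :] < k[:, None]
    day_idx = np.repeat(np.arange(n), k)
    hours = perm[mask]
    # sort hours within each day for tidy, order-stable output
    order = np.lexsort((hours, day_idx))
    return day_idx[order], hours[order]


def emit_hourly_steps(
    worn_flags,
    hours_mu: float,
    hours_sd: float,
    steps_per_worn_hour_mean: float,
    rng,
    dates=None,
) -> pd.DataFrame:
    """Hourly step rows for a run of consecutive days.

    Each worn day receives ``k`` distinct hours with at least one step
    (``k ~ round(Normal(hours_mu, hours_sd))`` clipped to [1, 24], steps
    Poisson floored at 1 so presence encodes wear); unworn days receive no
    rows.  ``dates`` defaults to consecutive days from 2020-01-01.
    """
    worn_flags = np.asarray(worn_flags, dtype=bool)
    if dates is None:
        dates = pd.date_range("2020-01-01", periods=len(worn_flags), freq="D")
    else:
        dates = pd.DatetimeIndex(dates)
        if len(dates) != len(worn_flags):
            raise ValueError("dates and worn_flags must be aligned")
    worn_idx = np.flatnonzero(worn_flags)
    k = _draw_worn_hour_counts(len(worn_idx), hours_mu, hours_sd, rng)
    day_idx, hours = _choose_distinct_hours(k, rng)
    steps = np.maximum(rng.poisson(steps_per_worn_hour_mean, size=len(hours)), 1)
    return pd.DataFrame(
        {
            "date": dates[worn_idx[day_idx]],
            "hour": hours.astype(np.int64),
            "steps": steps.astype(np.int64),
        }
    )


# ---------------------------------------------------------------------------
# Frailty location adjustment
# ---------------------------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(64)


def _expit_normal_mean(mu: float, sigma: float) -> float:
    """E[expit(mu + sigma Z)] for Z ~ N(0,1), by Gauss-Hermite quadrature."""
    z = np.sqrt(2.0) * sigma * _GH_NODES + mu
    return float(np.dot(_GH_WEIGHTS, expit(z)) / np.sqrt(np.pi))


@lru_cache(maxsize=256)
def mean_preserving_logit_mu(p: float, sigma: float) -> float:
    """Location mu such that E[expit(mu + sigma Z)] = p.

    With an additive logit-scale frailty the naive choice mu = logit(p)
    shrinks the population mean toward 1/2; this inversion keeps the
    cohort-period mean worn probability at the configured value.
    """
    if sigma == 0.0 or p in (0.0, 1.0):
        return float(logit(p)) if 0.0 < p < 1.0 else (np.inf if p == 1.0 else -np.inf)
    lo = float(logit(p)) - 5.0 * sigma - 1.0
    hi = float(logit(p)) + 5.0 * sigma + 1.0
    return float(brentq(lambda m: _expit_normal_mean(m, sigma) - p, lo, hi,
                        xtol=1e-12))


def _person_worn_prob(p: float, sigma: float, frailty: float) -> float:
    if p in (0.0, 1.0) or sigma == 0.0:
        return p
    return float(expit(mean_preserving_logit_mu(p, sigma) + frailty))


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate(config: SimConfig) -> SyntheticBundle:
    """Generate a full synthetic cohort; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_ppd + config.n_nonppd
    sigma = config.person_frailty_sd

    person_rows, event_rows, truth_rows = [], [], []
    step_pids, step_dates, step_hours, step_counts = [], [], [], []
    sleep_pids, sleep_dates = [], []

    for i in range(n):
        pid = f"P{i + 1:05d}"
        cohort = PPD if i < config.n_ppd else NONPPD

        delivery = _BASE_DATE + int(rng.integers(0, 365)) * _DAY
        preg_start = delivery - config.pregnancy_len_days * _DAY

        event_rows.append((pid, EV_PREGNANCY_START, preg_start, "SYN-PREG"))
        event_rows.append((pid, EV_DELIVERY, delivery, "SYN-DELIV"))

        if cohort == PPD:
            delay = float(
                rng.lognormal(np.log(config.ppd_delay_median_days),
                              config.ppd_delay_sigma)
            )
            delay = int(np.clip(np.rint(delay), 1, 730))
            ev_type = PPD_QUALIFYING_EVENTS[int(rng.integers(0, 3))]
            index = delivery + delay * _DAY
            event_rows.append((pid, ev_type, index, "SYN-PPD"))
        else:
            index = delivery + NONPPD_INDEX_OFFSET_DAYS * _DAY

        windows = periods.compute_windows_for_person(
            pid, cohort, preg_start, delivery, index
        )
        frailty = float(rng.normal(0.0, sigma)) if sigma > 0 else 0.0

        # simulate worn flags over the contiguous span of the four windows
        span_start = windows["start_date"].min()
        flags_parts, p_person = [], {}
        for row in windows.itertuples(index=False):
            p_eff = _person_worn_prob(
                config.wear_prob[(cohort, row.period)], sigma, frailty
            )
            p_person[row.period] = p_eff
            n_days = (row.end_date - row.start_date).days
            flags_parts.append(
                simulate_wear_sequence(n_days, p_eff, config.persistence_rho, rng)
            )
        flags = np.concatenate(flags_parts)
        dates = pd.date_range(span_start, periods=len(flags), freq="D")

        # device ownership: no data before the first-wear date
        nonempty_start = windows.loc[
            periods.window_lengths(windows) > 0, "start_date"
        ].min()
        if config.first_wear == "uniform":
            prepreg = windows[windows["period"] == "prepregnancy"].iloc[0]
            prepreg_len = (prepreg["end_date"] - prepreg["start_date"]).days
            if prepreg_len > 0:
                offset = int(rng.integers(0, prepreg_len))
                first_wear = prepreg["start_date"] + offset * _DAY
            else:
                first_wear = nonempty_start
        else:
            first_wear = nonempty_start
        flags &= np.asarray(dates >= first_wear)

        # between-person variation in habitual wear duration: person-level
        # offset on the mean worn hours (drawn even when flags are all off
        # so the rng stream does not depend on wear outcomes)
        hours_offset = (
            float(rng.normal(0.0, config.hours_person_sd))
            if config.hours_person_sd > 0 else 0.0
        )
        hourly = emit_hourly_steps(
            flags,
            float(np.clip(config.hours_mu + hours_offset, 1.0, 24.0)),
            config.hours_sd,
            config.steps_per_worn_hour_mean,
            rng,
            dates=dates,
        )
        step_pids.append(np.repeat(pid, len(hourly)))
        step_dates.append(hourly["date"].to_numpy())
        step_hours.append(hourly["hour"].to_numpy())
        step_counts.append(hourly["steps"].to_numpy())

        worn_dates = dates[flags]
        has_sleep = rng.random(len(worn_dates)) < config.sleep_given_worn
        sleep_on = worn_dates[has_sleep]
        sleep_pids.append(np.repeat(pid, len(sleep_on)))
        sleep_dates.append(np.asarray(sleep_on))

        age = float(np.round(rng.uniform(*config.age_range), 1))
        race = config.race_levels[
            int(rng.choice(len(config.race_levels), p=config.race_probs))
        ]
        income = config.income_levels[
            int(rng.choice(len(config.income_levels), p=config.income_probs))
        ]
        person_rows.append((pid, age, race, income))
        truth_rows.append(
            (pid, cohort, frailty, first_wear, preg_start, delivery, index)
            + tuple(p_person[per] for per in PERIODS)
        )

    persons = pd.DataFrame(
        person_rows,
        columns=["person_id", "age_at_index_years", "race_ethnicity",
                 "income_level"],
    )
    events = pd.DataFrame(
        event_rows, columns=["person_id", "event_type", "event_date", "code"]
    )
    steps = pd.DataFrame(
        {
            "person_id": np.concatenate(step_pids) if step_pids else [],
            "date": pd.DatetimeIndex(
                np.concatenate(step_dates) if step_dates else []
            ),
            "hour": np.concatenate(step_hours).astype(np.int64)
            if step_hours else [],
            "steps": np.concatenate(step_counts).astype(np.int64)
            if step_counts else [],
        }
    )
    sleep = pd.DataFrame(
        {
            "person_id": np.concatenate(sleep_pids) if sleep_pids else [],
            "sleep_date": pd.DatetimeIndex(
                np.concatenate(sleep_dates) if sleep_dates else []
            ),
            "is_main_sleep": True,
        }
    )
    if sleep.empty:
        sleep = pd.DataFrame(
            columns=["person_id", "sleep_date", "is_main_sleep"]
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["person_id", "cohort", "frailty", "first_wear_date",
                 "pregnancy_start_date", "delivery_date", "index_date"]
        + [f"p_{per}" for per in PERIODS],
    )
    return SyntheticBundle(persons, events, steps, sleep, truth)
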