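"""Statistical comparisons between PPD and non-PPD cohorts.

Four analysis families, each Bonferroni-corrected over its four tests:

* per-period covariate-adjusted cohort means of percent-worn (and the strict
  and worn-to-sleep variants) by ordinary least squares, with cohort means
  reported as estimated marginal means (EMMs) over a reference grid balanced
  across categorical covariate levels and age fixed at its sample mean;
* per-period comparison of hours worn per worn day via a linear mixed model
  with a person random intercept (repeated daily measurements), fit by REML,
  cohort effect tested with a normal (Wald) approximation;
* within-cohort Pearson correlations of percent-worn across period pairs,
  with Fisher-z confidence intervals;
* the same correlations for the wear-consistency statistic (maximum run of
  consecutive worn days).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from patsy import build_design_matrices
from scipy import stats
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .constants import COHORTS, NONPPD, PPD, PREPREGNANCY, PREGNANCY, PPD_PERIOD

DEFAULT_COVARIATES = ("age_at_index_years", "race_ethnicity", "income_level")
_CATEGORICAL = ("race_ethnicity", "income_level")


@dataclass
class AdjustedComparison:
    outcome: str
    period: str
    mean_ppd: float
    ci_low_ppd: float
    ci_high_ppd: float
    mean_nonppd: float
    ci_low_nonppd: float
    ci_high_nonppd: float
    contrast: float
    p_value: float
    alpha_corrected: float
    significant: bool = field(init=False)
    n: int = 0

    def __post_init__(self):
        self.significant = bool(self.p_value < self.alpha_corrected)


@dataclass
class CorrelationResult:
    cohort: str
    x_period: str
    y_period: str
    statistic: str
    r: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    alpha_corrected: float = np.nan
    significant: bool = False


# ---------------------------------------------------------------------------
# Multiple-testing correction
# ---------------------------------------------------------------------------

def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha/m; decisions use the unrounded value."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0,1], got {alpha}")
    if m < 1:
        raise ValueError(f"family size m must be >= 1, got {m}")
    return alpha / m


def display_threshold(value: float) -> str:
    """Three-decimal display form in journal style (0.0125 -> '.013')."""
    s = f"{value:.3f}"
    return s[1:] if s.startswith("0.") else s


# ---------------------------------------------------------------------------
# Covariate handling
# ---------------------------------------------------------------------------

def _check_levels(data: pd.DataFrame, covariates) -> None:
    for cov in covariates:
        if cov not in _CATEGORICAL or cov not in data.columns:
            continue
        counts = data[cov].value_counts()
        singles = counts[counts == 1]
        if not singles.empty:
            raise ValueError(
                f"covariate {cov!r} has level(s) {list(singles.index)} present "
                "in only one row; collapse refused — re-level or merge these "
                "levels before fitting"
            )


def _check_rank(exog: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        _, r = np.linalg.qr(exog)
        aliased = [names[j] for j in range(exog.shape[1])
                   if abs(r[j, j]) < 1e-8]
        raise ValueError(f"singular design matrix; aliased columns: {aliased}")


def _formula(outcome: str, covariates) -> str:
    terms = [f"C(cohort, Treatment(reference='{NONPPD}'))"]
    for cov in covariates:
        terms.append(f"C({cov})" if cov in _CATEGORICAL else cov)
    return f"{outcome} ~ " + " + ".join(terms)


def _cohort_param(names) -> str:
    hits = [n for n in names if n.startswith("C(cohort")]
    if len(hits) != 1:
        raise RuntimeError(f"expected one cohort coefficient, found {hits}")
    return hits[0]


def _reference_grid(data: pd.DataFrame, covariates) -> pd.DataFrame:
    """Balanced grid: cohorts x all categorical levels, age at sample mean."""
    axes = {"cohort": list(COHORTS)}
    means = {}
    for cov in covariates:
        if cov in _CATEGORICAL:
            axes[cov] = sorted(data[cov].dropna().unique())
        else:
            means[cov] = float(data[cov].mean())
    grid = pd.DataFrame(
        list(itertools.product(*axes.values())), columns=list(axes)
    )
    for cov, m in means.items():
        grid[cov] = m
    return grid


def _emm(design_info, params, cov_params, data, covariates, alpha=0.05):
    """Estimated marginal mean, CI (normal quantiles) per cohort."""
    grid = _reference_grid(data, covariates)
    (X,) = build_design_matrices([design_info], grid)
    X = np.asarray(X)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    out = {}
    for cohort in COHORTS:
        mask = (grid["cohort"] == cohort).to_numpy()
        ell = X[mask].mean(axis=0)
        est = float(ell @ params)
        se = float(np.sqrt(ell @ cov_params @ ell))
        out[cohort] = (est, est - z * se, est + z * se)
    return out


# ---------------------------------------------------------------------------
# Cross-sectional adjusted comparison (OLS)
# ---------------------------------------------------------------------------

def adjusted_group_means(
    summaries: pd.DataFrame,
    outcome: str,
    period: str,
    covariates=DEFAULT_COVARIATES,
    alpha: float = 0.05,
    alpha_corrected: float | None = None,
) -> AdjustedComparison:
    """Covariate-adjusted cohort means of a per-person period summary.

    OLS of the outcome on cohort + covariates (treatment coding); per-cohort
    EMMs over a balanced reference grid; two-sided p for the cohort contrast
    from the OLS t-test.
    """
    data = summaries[summaries["period"] == period].dropna(subset=[outcome])
    counts = data["cohort"].value_counts()
    if any(counts.get(c, 0) < 2 for c in COHORTS):
        raise ValueError(
            f"period {period!r}: need >= 2 persons per cohort, have "
            f"{counts.to_dict()}"
        )
    _check_levels(data, covariates)
    model = smf.ols(_formula(outcome, covariates), data=data)
    _check_rank(model.exog, model.exog_names)
    res = model.fit()
    emms = _emm(
        res.model.data.design_info, res.params.to_numpy(),
        res.cov_params().to_numpy(), data, covariates, alpha,
    )
    cname = _cohort_param(res.model.exog_names)
    if alpha_corrected is None:
        alpha_corrected = alpha
    return AdjustedComparison(
        outcome=outcome,
        period=period,
        mean_ppd=emms[PPD][0], ci_low_ppd=emms[PPD][1], ci_high_ppd=emms[PPD][2],
        mean_nonppd=emms[NONPPD][0], ci_low_nonppd=emms[NONPPD][1],
        ci_high_nonppd=emms[NONPPD][2],
        contrast=float(res.params[cname]),
        p_value=float(res.pvalues[cname]),
        alpha_corrected=alpha_corrected,
        n=int(len(data)),
    )


# ---------------------------------------------------------------------------
# Daily-hours mixed model
# ---------------------------------------------------------------------------

def mixed_hours_model(
    hours_rows: pd.DataFrame,
    period: str,
    covariates=DEFAULT_COVARIATES,
    alpha: float = 0.05,
    alpha_corrected: float | None = None,
    outcome: str = "hours_worn",
) -> AdjustedComparison:
    """Hours worn per worn day: person-random-intercept linear mixed model.

    ``hours_rows`` holds one row per worn person-day with the outcome,
    cohort and covariates.  REML fit; the cohort p-value uses the normal
    (Wald) approximation.
    """
    data = hours_rows[hours_rows["period"] == period].dropna(subset=[outcome])
    counts = data.groupby("cohort")["person_id"].nunique()
    if any(counts.get(c, 0) < 2 for c in COHORTS):
        raise ValueError(
            f"period {period!r}: need >= 2 persons per cohort, have "
            f"{counts.to_dict()}"
        )
    _check_levels(data.drop_duplicates("person_id"), covariates)
    model = smf.mixedlm(
        _formula(outcome, covariates), data=data, groups=data["person_id"]
    )
    _check_rank(model.exog, model.exog_names)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        res = model.fit(reml=True)
        if not res.converged:
            # gradient methods occasionally stall on the REML surface;
            # Powell is slower but reliable here
            res = model.fit(reml=True, method="powell", maxiter=2000)
    # A zero random-intercept variance sits on the boundary of the parameter
    # space, where the optimizer legitimately stops without a zero gradient;
    # only treat it as a failure when the variance estimate is interior.
    boundary = float(res.cov_re.iloc[0, 0]) < 1e-4 * float(res.scale)
    if not res.converged and not boundary:
        raise RuntimeError(
            "mixed model did not converge; optimizer output: "
            f"{res.summary().tables[0]}"
        )
    fe_names = list(res.model.exog_names)
    params = res.fe_params.to_numpy()
    cov_fe = res.cov_params().loc[fe_names, fe_names].to_numpy()
    emms = _emm(
        res.model.data.design_info, params, cov_fe, data, covariates, alpha
    )
    cname = _cohort_param(fe_names)
    est = float(res.fe_params[cname])
    se = float(res.bse_fe[cname])
    p = 2.0 * stats.norm.sf(abs(est / se))
    if alpha_corrected is None:
        alpha_corrected = alpha
    return AdjustedComparison(
        outcome="hours_per_worn_day",
        period=period,
        mean_ppd=emms[PPD][0], ci_low_ppd=emms[PPD][1], ci_high_ppd=emms[PPD][2],
        mean_nonppd=emms[NONPPD][0], ci_low_nonppd=emms[NONPPD][1],
        ci_high_nonppd=emms[NONPPD][2],
        contrast=est,
        p_value=float(p),
        alpha_corrected=alpha_corrected,
        n=int(len(data)),
    )


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def pearson_with_ci(
    x, y, alpha: float = 0.05, **labels
) -> CorrelationResult:
    """Sample Pearson r with Fisher-z CI and t-distribution p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-d vectors")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite")
    n = len(x)
    if n < 3:
        raise ValueError(f"need n >= 3 paired observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector: correlation undefined")
    r, p = stats.pearsonr(x, y)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(n - 3)
    q = stats.norm.ppf(1.0 - alpha / 2.0)
    lo, hi = np.tanh(z - q * se), np.tanh(z + q * se)
    return CorrelationResult(
        cohort=labels.get("cohort", ""),
        x_period=labels.get("x_period", ""),
        y_period=labels.get("y_period", ""),
        statistic=labels.get("statistic", ""),
        r=float(r), ci_low=float(lo), ci_high=float(hi),
        p_value=float(p), n=n,
    )


# ---------------------------------------------------------------------------
# Whole-analysis drivers
# ---------------------------------------------------------------------------

OLS_OUTCOMES = ("pct_worn", "pct_worn_strict", "pct_sleep")
CORR_PAIRS = ((PREPREGNANCY, PPD_PERIOD), (PREGNANCY, PPD_PERIOD))
CORR_STATISTICS = ("pct_worn", "max_consecutive_worn")


def compare_all(
    summaries: pd.DataFrame,
    worn_day_hours: pd.DataFrame,
    assignments: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    alpha: float = 0.05,
    family_size: int = 4,
    periods_order=("prepregnancy", "pregnancy", "postpartum", "ppd"),
) -> pd.DataFrame:
    """All per-period cohort comparisons as one tidy table."""
    meta_cols = ["person_id", "cohort"] + [c for c in covariates]
    meta = assignments[meta_cols]
    s = summaries.merge(meta, on="person_id")
    h = worn_day_hours.merge(meta, on="person_id")
    alpha_c = bonferroni_threshold(alpha, family_size)
    rows = []
    for outcome in OLS_OUTCOMES:
        for period in periods_order:
            rows.append(
                adjusted_group_means(
                    s, outcome, period, covariates, alpha, alpha_c
                ).__dict__
            )
    for period in periods_order:
        rows.append(
            mixed_hours_model(h, period, covariates, alpha, alpha_c).__dict__
        )
    return pd.DataFrame(rows)


def correlate_all(
    summaries: pd.DataFrame,
    assignments: pd.DataFrame,
    alpha: float = 0.05,
    family_size: int = 4,
) -> pd.DataFrame:
    """Within-cohort cross-period correlations for both wear statistics.

    Each statistic forms one family of four tests (two period pairings by
    two cohorts), Bonferroni-corrected together.
    """
    s = summaries.merge(assignments[["person_id", "cohort"]], on="person_id")
    alpha_c = bonferroni_threshold(alpha, family_size)
    rows = []
    for statistic in CORR_STATISTICS:
        wide = s.pivot_table(
            index=["person_id", "cohort"], columns="period", values=statistic
        ).reset_index()
        for cohort in COHORTS:
            for x_period, y_period in CORR_PAIRS:
                sub = wide[wide["cohort"] == cohort].dropna(
                    subset=[x_period, y_period]
                )
                res = pearson_with_ci(
                    sub[x_period], sub[y_period], alpha,
                    cohort=cohort, x_period=x_period, y_period=y_period,
                    statistic=statistic,
                )
                res.alpha_corrected = alpha_c
                res.significant = bool(res.p_value < alpha_c)
                rows.append(res.__dict__)
    return pd.DataFrame(rows)
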