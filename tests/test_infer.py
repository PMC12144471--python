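"""Inference contracts: EMM reductions, equivariance, mixed-model
degeneracy, Fisher-z intervals, and the Bonferroni threshold."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ppdwear import infer
from ppdwear.constants import NONPPD, PPD


def make_summaries(rng, n_per_cohort=40, diff=0.0, period="ppd",
                   balanced=False, sd=10.0):
    """Per-person percent-worn rows with covariates for both cohorts."""
    rows = []
    races = ["w", "b", "h"]
    incomes = ["low", "mid", "high"]
    for cohort, base in ((PPD, 50.0 + diff), (NONPPD, 50.0)):
        for i in range(n_per_cohort):
            if balanced:
                race = races[i % len(races)]
                income = incomes[(i // len(races)) % len(incomes)]
                age = 25.0 + (i % 10)
            else:
                race = races[int(rng.integers(len(races)))]
                income = incomes[int(rng.integers(len(incomes)))]
                age = float(rng.uniform(20, 40))
            rows.append({
                "person_id": f"{cohort}-{i}", "cohort": cohort,
                "period": period,
                "pct_worn": float(np.clip(base + rng.normal(0, sd), 0, 100)),
                "age_at_index_years": age,
                "race_ethnicity": race, "income_level": income,
            })
    return pd.DataFrame(rows)


class TestAdjustedGroupMeans:
    def test_no_covariates_reduces_to_group_means_and_ttest(self, rng):
        data = make_summaries(rng, diff=8.0)
        res = infer.adjusted_group_means(data, "pct_worn", "ppd",
                                         covariates=())
        raw = data.groupby("cohort")["pct_worn"].mean()
        assert res.mean_ppd == pytest.approx(raw[PPD], abs=1e-10)
        assert res.mean_nonppd == pytest.approx(raw[NONPPD], abs=1e-10)
        t = stats.ttest_ind(
            data.loc[data.cohort == PPD, "pct_worn"],
            data.loc[data.cohort == NONPPD, "pct_worn"],
        )
        assert res.p_value == pytest.approx(t.pvalue, rel=1e-9)

    def test_balanced_covariates_leave_means_unchanged(self, rng):
        data = make_summaries(rng, diff=5.0, balanced=True, n_per_cohort=36)
        adj = infer.adjusted_group_means(data, "pct_worn", "ppd")
        raw = data.groupby("cohort")["pct_worn"].mean()
        assert adj.mean_ppd == pytest.approx(raw[PPD], abs=1e-10)
        assert adj.mean_nonppd == pytest.approx(raw[NONPPD], abs=1e-10)

    def test_shift_equivariance(self, rng):
        data = make_summaries(rng, diff=5.0)
        base = infer.adjusted_group_means(data, "pct_worn", "ppd")
        shifted = data.assign(pct_worn=data["pct_worn"] + 7.5)
        res = infer.adjusted_group_means(shifted, "pct_worn", "ppd")
        assert res.mean_ppd == pytest.approx(base.mean_ppd + 7.5, abs=1e-8)
        assert res.mean_nonppd == pytest.approx(base.mean_nonppd + 7.5,
                                                abs=1e-8)
        assert res.p_value == pytest.approx(base.p_value, abs=1e-10)
        assert res.contrast == pytest.approx(base.contrast, abs=1e-8)

    def test_ci_brackets_mean(self, rng):
        res = infer.adjusted_group_means(make_summaries(rng, diff=5.0),
                                         "pct_worn", "ppd")
        assert res.ci_low_ppd <= res.mean_ppd <= res.ci_high_ppd
        assert res.ci_low_nonppd <= res.mean_nonppd <= res.ci_high_nonppd
        assert 0 <= res.p_value <= 1

    def test_singleton_level_refused(self, rng):
        data = make_summaries(rng)
        data.loc[data.index[0], "race_ethnicity"] = "only-once"
        with pytest.raises(ValueError, match="re-level"):
            infer.adjusted_group_means(data, "pct_worn", "ppd")

    def test_singular_design_names_aliased_columns(self, rng):
        data = make_summaries(rng)
        data["income_level"] = np.where(data["cohort"] == PPD, "low", "high")
        with pytest.raises(ValueError, match="aliased"):
            infer.adjusted_group_means(data, "pct_worn", "ppd")

    def test_too_few_persons_rejected(self, rng):
        data = make_summaries(rng, n_per_cohort=1)
        with pytest.raises(ValueError, match="2 persons"):
            infer.adjusted_group_means(data, "pct_worn", "ppd",
                                       covariates=())

    def test_unadjusted_and_adjusted_agree_with_independent_covariates(
            self, rng):
        # covariates independent of cohort: adjustment is unbiased for the
        # same contrast, so the two estimates agree on average
        diffs = []
        for _ in range(150):
            data = make_summaries(rng, n_per_cohort=30, diff=10.0)
            adj = infer.adjusted_group_means(data, "pct_worn", "ppd")
            raw = infer.adjusted_group_means(data, "pct_worn", "ppd",
                                             covariates=())
            diffs.append(adj.contrast - raw.contrast)
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 3 * se + 1e-9


def make_hours_rows(rng, n_per_cohort=30, days=8, person_sd=1.5, diff=0.0,
                    noise_sd=3.0):
    rows = []
    for cohort, base in ((PPD, 16.0 + diff), (NONPPD, 16.0)):
        for i in range(n_per_cohort):
            mu_i = base + rng.normal(0, person_sd)
            for d in range(days):
                rows.append({
                    "person_id": f"{cohort}-{i}", "cohort": cohort,
                    "period": "ppd",
                    "hours_worn": float(
                        np.clip(mu_i + rng.normal(0, noise_sd), 1, 24)
                    ),
                    "age_at_index_years": float(rng.uniform(20, 40)),
                    "race_ethnicity": "x", "income_level": "y",
                })
    return pd.DataFrame(rows)


class TestMixedHoursModel:
    def test_zero_between_person_variance_matches_ols(self, rng):
        data = make_hours_rows(rng, person_sd=0.0, diff=2.0, noise_sd=2.0)
        mixed = infer.mixed_hours_model(data, "ppd", covariates=())
        ols = infer.adjusted_group_means(data, "hours_worn", "ppd",
                                         covariates=())
        assert mixed.contrast == pytest.approx(ols.contrast, abs=1e-6)
        assert mixed.mean_ppd == pytest.approx(ols.mean_ppd, abs=1e-6)
        assert mixed.mean_nonppd == pytest.approx(ols.mean_nonppd, abs=1e-6)

    def test_recovers_cohort_difference(self, rng):
        data = make_hours_rows(rng, n_per_cohort=100, diff=2.0)
        res = infer.mixed_hours_model(data, "ppd", covariates=())
        assert res.contrast == pytest.approx(2.0, abs=0.8)
        assert res.ci_low_ppd <= res.mean_ppd <= res.ci_high_ppd


class TestPearsonWithCI:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        res = infer.pearson_with_ci(x, x)
        assert res.r == pytest.approx(1.0)
        assert res.p_value < 1e-10

    def test_null_monte_carlo(self, rng):
        n = 5000
        res = infer.pearson_with_ci(rng.normal(size=n), rng.normal(size=n))
        assert abs(res.r) < 3.0 / np.sqrt(n)
        assert res.ci_low <= res.r <= res.ci_high

    def test_errors(self, rng):
        with pytest.raises(ValueError, match="n >= 3"):
            infer.pearson_with_ci([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="constant"):
            infer.pearson_with_ci([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="finite"):
            infer.pearson_with_ci([1.0, np.nan, 3.0], [1.0, 2.0, 3.0])

    def test_ci_monotone_in_r_and_shrinks_with_n(self):
        rs = [-0.5, 0.0, 0.4, 0.8]
        lows, highs = [], []
        for r in rs:
            # synthesize exact-r samples via a rotation trick
            n = 40
            x = np.linspace(-1, 1, n)
            e = np.sin(np.linspace(0, 23, n) * 7)  # fixed, uncorrelated-ish
            e = e - e.mean()
            e = e - x * (e @ x) / (x @ x)  # orthogonalize
            y = r * x / np.std(x) + np.sqrt(1 - r**2) * e / np.std(e)
            res = infer.pearson_with_ci(x, y)
            assert res.r == pytest.approx(r, abs=1e-10)
            lows.append(res.ci_low)
            highs.append(res.ci_high)
        assert lows == sorted(lows)
        assert highs == sorted(highs)
        wide = infer.pearson_with_ci(np.arange(10.0),
                                     np.arange(10.0) ** 2)
        narrow_x = np.tile(np.arange(10.0), 10) + np.arange(100) * 1e-6
        narrow = infer.pearson_with_ci(narrow_x, narrow_x ** 2)
        assert (narrow.ci_high - narrow.ci_low) < (wide.ci_high - wide.ci_low)


class TestBonferroni:
    def test_four_tests(self):
        t = infer.bonferroni_threshold(0.05, 4)
        assert t == pytest.approx(0.0125)
        assert infer.display_threshold(t) == ".013"

    def test_identity(self):
        assert infer.bonferroni_threshold(0.05, 1) == pytest.approx(0.05)

    def test_direct_division(self):
        assert infer.bonferroni_threshold(0.01, 10) == pytest.approx(0.001)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            infer.bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            infer.bonferroni_threshold(0.0, 4)
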