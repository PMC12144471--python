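"""Shared simulation helper for the large-n contrast-pattern check.

Person-level percent-worn is simulated as a beta-distributed worn
probability (mean at the reported per-period adjusted means, concentration
chosen so the between-person sd is ~43 percentage points, matching the
dispersion implied by the reported confidence intervals) with binomial
day-to-day noise over realistic period lengths.
"""

import numpy as np
import pandas as pd

from ppdwear import infer
from ppdwear.constants import NONPPD, PPD

TRUE_MEANS = {
    PPD: {"prepregnancy": 0.475, "pregnancy": 0.468,
          "postpartum": 0.699, "ppd": 0.666},
    NONPPD: {"prepregnancy": 0.486, "pregnancy": 0.405,
             "postpartum": 0.500, "ppd": 0.464},
}
PERIOD_DAYS = {"prepregnancy": 400, "pregnancy": 270,
               "postpartum": 50, "ppd": 45}
BETA_CONCENTRATION = 0.35  # between-person sd ~0.43 at p=0.5


def simulate_percent_worn_cohorts(n_per_cohort: int, seed: int) -> dict:
    """Per-period cohort comparisons at the corrected threshold.

    Returns {period: significant_at_alpha_over_4}.
    """
    rng = np.random.default_rng(seed)
    alpha_c = infer.bonferroni_threshold(0.05, 4)
    significant = {}
    for period, n_days in PERIOD_DAYS.items():
        rows = []
        for cohort in (PPD, NONPPD):
            p = TRUE_MEANS[cohort][period]
            person_p = rng.beta(p * BETA_CONCENTRATION,
                                (1 - p) * BETA_CONCENTRATION,
                                size=n_per_cohort)
            pct = 100.0 * rng.binomial(n_days, person_p) / n_days
            rows.extend(
                {"person_id": f"{cohort}{i}", "cohort": cohort,
                 "period": period, "pct_worn": float(pct[i])}
                for i in range(n_per_cohort)
            )
        res = infer.adjusted_group_means(
            pd.DataFrame(rows), "pct_worn", period,
            covariates=(), alpha_corrected=alpha_c,
        )
        significant[period] = res.significant
    return significant
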