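import numpy as np
import pandas as pd
import pytest

from ppdwear import SimConfig, generate, periods, phenotype


@pytest.fixture(scope="session")
def small_config():
    # Small cohort with short worn-day step streams: fast, but exercises
    # every stage (frailty, persistence, first-wear clipping, sleep).
    return SimConfig(
        n_ppd=12,
        n_nonppd=18,
        hours_mu=3.0,
        hours_sd=1.0,
        steps_per_worn_hour_mean=50.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_bundle):
    """(assignments, clipped windows) for the small synthetic cohort."""
    assignments, _ = phenotype.assign_cohorts(
        small_bundle.events, small_bundle.persons
    )
    windows = periods.compute_windows(assignments)
    first = small_bundle.steps.groupby("person_id")["date"].min()
    windows = periods.clip_to_first_wear(windows, first)
    assignments, _ = phenotype.filter_eligible(
        assignments, small_bundle.steps, windows
    )
    windows = windows[windows["person_id"].isin(assignments["person_id"])]
    return assignments, windows.reset_index(drop=True)


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
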