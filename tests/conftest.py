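import numpy as np
import pandas as pd
import pytest

from chewmix.synth import CohortSpec, WaferSpec, generate_cohort, generate_wafer

COHORT_COLUMNS = ["subject_id", "age", "age_group", "sex", "dental_status",
                  "cgc", "session", "vhh"]


@pytest.fixture(scope="session")
def default_wafer():
    """One default noisy wafer image with its ground-truth mask."""
    return generate_wafer(WaferSpec(seed=7))


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-subject synthetic cohort (fast, non-degenerate)."""
    return generate_cohort(CohortSpec(n_subjects=60, seed=5))


def make_cohort(n_per_group, k=3, seed=0, group_effects=(0.0, 0.0, 0.0),
                session_effects=(0.0, 0.0, 0.0), subject_sd=1.0, noise_sd=1.0,
                within_corr=None, baseline=100.0):
    """Hand-rolled cohort builder for statistical tests.

    ``within_corr`` (k x k) draws session residuals from a multivariate
    normal instead of iid noise, for non-spherical nulls.
    """
    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    for g, n in enumerate(n_per_group):
        for _ in range(n):
            sid += 1
            b = rng.normal(0.0, subject_sd)
            if within_corr is not None:
                eps = rng.multivariate_normal(np.zeros(k),
                                              noise_sd ** 2 * np.asarray(within_corr))
            else:
                eps = rng.normal(0.0, noise_sd, size=k)
            for s in range(1, k + 1):
                y = (baseline + group_effects[g] + session_effects[s - 1]
                     + b + eps[s - 1])
                rows.append((f"P{sid:04d}", 30 + g, 2, "female", "natural",
                             g, s, y))
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)
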