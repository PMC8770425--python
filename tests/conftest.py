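"""Shared fixtures: one small synthetic cohort processed end-to-end.

The cohort and its derived products are session-scoped because windowed
graphical-LASSO estimation over all subjects is the expensive step; tests
treat them as read-only.
"""

from __future__ import annotations

import numpy as np
import pytest

from dfcstates import (
    PipelineConfig,
    SyntheticCohortSpec,
    compute_windowed_fc,
    load_roi_table,
    make_taper,
    run_baseline,
    simulate_cohort,
)

COHORT_SEED = 11
FIXED_LAMBDA = 0.1


@pytest.fixture(scope="session")
def atlas():
    return load_roi_table()


@pytest.fixture(scope="session")
def cohort():
    spec = SyntheticCohortSpec(n_mdd=8, n_hc=8, n_post=8, seed=COHORT_SEED)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def baseline_windowed(cohort):
    taper = make_taper()
    return {
        ts.subject_id: compute_windowed_fc(ts, taper, lam=FIXED_LAMBDA, tol=1e-3)
        for ts in cohort.sessions("baseline")
    }


@pytest.fixture(scope="session")
def pipeline_config():
    return PipelineConfig(
        lambda_fixed=FIXED_LAMBDA, k_fixed=4, n_init=10, n_perm=200, seed=5
    )


@pytest.fixture(scope="session")
def baseline_result(cohort, pipeline_config):
    return run_baseline(cohort.timeseries, cohort.clinical, pipeline_config)


def window_truth(path: np.ndarray, length: int = 22):
    """Planted label (window midpoint state) and purity flag per window."""
    n_win = len(path) - length + 1
    labels = np.array([path[w + length // 2] for w in range(n_win)])
    pure = np.array([np.all(path[w : w + length] == path[w]) for w in range(n_win)])
    return labels, pure
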