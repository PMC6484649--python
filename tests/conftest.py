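"""Shared fixtures: small simulated cohorts and count-encoded fixture tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hteharm.simulate import TRUTH_COLUMNS, generate_cohort, sprint_like_config


def cohort_from_counts(cells, n_sites: int = 5, covariates: dict | None = None) -> pd.DataFrame:
    """Synthetic trial table encoding exact per-cell participant/event counts.

    ``cells`` is a list of ``(arm, n, events)`` or ``(arm, n, events, extra)``
    tuples, where ``extra`` is a dict of constant covariate columns for that
    cell.  Times are spread deterministically so the table is a valid trial
    table; the synthetic fixture exists purely to reproduce printed counts.
    """
    rows = []
    pid = 1
    for cell in cells:
        arm, n, events = cell[:3]
        extra = cell[3] if len(cell) > 3 else {}
        for i in range(n):
            rows.append(
                {
                    "id": pid,
                    "site": pid % n_sites,
                    "arm": arm,
                    "time": 1.0 + 0.001 * pid,
                    "event": 1 if i < events else 0,
                    **(covariates or {}),
                    **extra,
                }
            )
            pid += 1
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """Simulated n=2000 trial-like cohort, planted subgroup, truth dropped."""
    cfg = sprint_like_config(n_participants=2000, seed=202, treatment_log_hr=0.0)
    return generate_cohort(cfg).drop(columns=list(TRUTH_COLUMNS))


@pytest.fixture(scope="session")
def null_cohort() -> pd.DataFrame:
    """Simulated n=2000 cohort with no treatment effect anywhere."""
    cfg = sprint_like_config(n_participants=2000, seed=303, planted=False, treatment_log_hr=0.0)
    return generate_cohort(cfg).drop(columns=list(TRUTH_COLUMNS))


def exponential_survival_frame(
    n: int,
    log_hr: float,
    seed: int,
    *,
    baseline: float = 0.05,
    n_sites: int = 20,
    censor_at: tuple[float, float] = (2.0, 5.0),
    subgroup_prevalence: float = 0.0,
    subgroup_log_hr: float = 0.0,
) -> pd.DataFrame:
    """Plain proportional-hazards benchmark data for the Cox engine tests."""
    rng = np.random.default_rng(seed)
    arm = rng.integers(0, 2, n)
    site = rng.integers(0, n_sites, n)
    sub = (rng.random(n) < subgroup_prevalence).astype(int)
    lam = baseline * np.exp(log_hr * arm + subgroup_log_hr * arm * sub)
    t = rng.exponential(1.0 / lam)
    c = rng.uniform(*censor_at, n)
    return pd.DataFrame(
        {
            "time": np.minimum(t, c),
            "event": (t <= c).astype(int),
            "arm": arm,
            "site": site,
            "sub": sub,
        }
    )
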