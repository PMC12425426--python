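import warnings

import numpy as np
import pandas as pd
import pytest

from actidep import SyntheticCohortConfig, generate_cohort

# feature warnings (constant columns etc.) are part of tested behaviour;
# keep unrelated sklearn convergence chatter out of the report
warnings.filterwarnings("ignore", message=".*ConvergenceWarning.*")


@pytest.fixture(scope="session")
def tiny_cohort():
    """4 + 4 participants x 2 days: enough for plumbing tests, fast."""
    cfg = SyntheticCohortConfig(
        n_condition=4, n_control=4, days_per_participant=2, seed=42
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """12 + 12 participants x 3 days with default planted effects."""
    cfg = SyntheticCohortConfig(
        n_condition=12, n_control=12, days_per_participant=3, seed=7
    )
    return generate_cohort(cfg)


def write_activity_csv(path, rows):
    """Write an activity CSV from (timestamp, date, activity) tuples."""
    pd.DataFrame(rows, columns=["timestamp", "date", "activity"]).to_csv(
        path, index=False
    )
    return path


def write_scores_csv(path, rows):
    cols = ["number", "days", "gender", "age", "afftype", "melanch",
            "inpatient", "edu", "marriage", "work", "madrs1", "madrs2"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(0)
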