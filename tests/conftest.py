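import numpy as np
import pandas as pd
import pytest

from agingphases import CohortConfig, OmicsMatrix, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across tests."""
    return generate_cohort(CohortConfig(seed=42))


@pytest.fixture(scope="session")
def clean_cohort():
    """Default cohort without the last-phase noise inflation, for
    analyses that need genes free of any phase signal."""
    return generate_cohort(CohortConfig(seed=42, phase4_noise_factor=1.0))


@pytest.fixture
def tiny_matrix():
    df = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [1.0, 1.0, 1.0, 1.0]],
        index=["GA", "GB", "GC"], columns=["S1", "S2", "S3", "S4"],
    )
    return OmicsMatrix(df, kind="expression", scale="log2_tpm")


def balanced_subset(cohort, seed=0):
    """Equal per-phase subject subset of a cohort's expression matrix."""
    truth = cohort.truth.phases
    rng = np.random.default_rng(seed)
    m = truth.value_counts().min()
    keep = []
    for p in sorted(truth.unique()):
        ids = truth.index[truth == p].to_numpy()
        keep += list(rng.choice(ids, size=m, replace=False))
    return cohort.expr.with_values(cohort.expr.values[keep]), truth.loc[keep]
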