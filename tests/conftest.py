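import numpy as np
import pandas as pd
import pytest

from semicompete.cohort import CohortTable


def make_cohort(df: pd.DataFrame) -> CohortTable:
    covs = [c for c in df.columns if c not in ("id", "y1", "delta1", "y2", "delta2")]
    return CohortTable(data=df.reset_index(drop=True), covariate_names=covs)


@pytest.fixture
def hand_cohort() -> CohortTable:
    """Ten subjects counted by hand: 4 with the non-terminal event (2 of
    whom died), 6 without (1 died)."""
    rows = [
        # id, y1, d1, y2, d2, x
        ("a1", 100.0, 1, 400.0, 1, 1.0),
        ("a2", 200.0, 1, 200.0, 1, 0.0),  # same-day illness and death
        ("a3", 150.0, 1, 900.0, 0, 1.0),
        ("a4", 50.0, 1, 600.0, 0, 0.0),
        ("b1", 300.0, 0, 300.0, 1, 1.0),
        ("b2", 500.0, 0, 500.0, 0, 0.0),
        ("b3", 250.0, 0, 250.0, 0, 1.0),
        ("b4", 700.0, 0, 700.0, 0, 0.0),
        ("b5", 800.0, 0, 800.0, 0, 1.0),
        ("b6", 120.0, 0, 120.0, 0, 0.0),
    ]
    df = pd.DataFrame(rows, columns=["id", "y1", "delta1", "y2", "delta2", "x"])
    return make_cohort(df)
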