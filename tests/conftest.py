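import numpy as np
import pandas as pd
import pytest

from cardioindex import Cohort, Variable


def make_uci_record(values: dict[int, float], default: float = 1.0) -> str:
    """One raw-dialect record: 75 numeric tokens + the `name` terminator.

    ``values`` maps 1-based attribute positions to values; everything
    else takes ``default``.  Tokens are wrapped over several physical
    lines the way the real files are.
    """
    tokens = [str(values.get(i, default)) for i in range(1, 76)] + ["name"]
    lines = [" ".join(tokens[i:i + 8]) for i in range(0, len(tokens), 8)]
    return "\n".join(lines) + "\n"


@pytest.fixture
def separable_df() -> pd.DataFrame:
    """Two well-separated Gaussian clouds: linearly separable labels."""
    rng = np.random.default_rng(42)
    n = 300
    y = np.repeat([0, 1], n // 2)
    x1 = rng.normal(0, 1, n) + 8 * y
    x2 = rng.normal(0, 1, n) + 8 * y
    return pd.DataFrame({"f1": x1, "f2": x2, "Y": y.astype(float)})


@pytest.fixture
def labelled_cohort() -> Cohort:
    """A tiny labelled cohort with vitals and one covariate."""
    df = pd.DataFrame({
        "sbp": [120.0, 150.0, 135.0, 160.0, 110.0, 142.0],
        "dbp": [80.0, 100.0, 85.0, 95.0, 70.0, 88.0],
        "hr": [70.0, 80.0, 75.0, 90.0, 65.0, 72.0],
        "V3": [50.0, 61.0, 55.0, 67.0, 48.0, 59.0],
        "Y": [0.0, 1.0, 0.0, 1.0, 0.0, 1.0],
    })
    return Cohort(df, {c: Variable(c, c) for c in df.columns if c != "Y"})
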