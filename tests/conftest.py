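"""Shared fixtures: small seeded matrices and survival tables."""

import numpy as np
import pandas as pd
import pytest


@pytest.fixture(scope="session")
def toy_beta():
    """8-sample x 5-CpG beta matrix with two classes and real signal.

    CpGs cg1/cg2 separate the classes; cg3-cg5 are noise.
    """
    rng = np.random.default_rng(17)
    cpgs = [f"cg{i}" for i in range(1, 6)]
    samples = [f"s{i}" for i in range(1, 9)]
    y = np.array(["AML"] * 4 + ["normal"] * 4)
    X = rng.uniform(0.2, 0.8, size=(5, 8))
    X[0, :4] += 0.15
    X[1, 4:] += 0.2
    return pd.DataFrame(X, index=cpgs, columns=samples), pd.Series(y, index=samples)


@pytest.fixture(scope="session")
def toy_surv():
    """8 subjects with a mix of events and censoring (months)."""
    return pd.DataFrame(
        {
            "sample_id": [f"p{i}" for i in range(1, 9)],
            "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0],
            "event": [1, 0, 1, 1, 0, 1, 1, 0],
        }
    )


@pytest.fixture(scope="session")
def surv_cohort():
    """A 200-patient survival cohort with a binary risk covariate."""
    rng = np.random.default_rng(99)
    n = 200
    group = rng.integers(0, 2, size=n)
    hazard = 0.02 * np.exp(1.0 * group)
    t = rng.exponential(1.0 / hazard)
    c = rng.uniform(0, 120, size=n)
    surv = pd.DataFrame(
        {
            "sample_id": [f"p{i}" for i in range(n)],
            "time": np.minimum(t, c),
            "event": (t <= c).astype(int),
        }
    )
    return surv, group
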