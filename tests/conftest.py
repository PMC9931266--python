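import warnings

import numpy as np
import pandas as pd
import pytest

from cdivet.synth_cohort import Cohort

warnings.filterwarnings("ignore", message="single-class input")


@pytest.fixture
def rng():
    return np.random.default_rng(20220808)


@pytest.fixture
def tiny_cohort():
    """Eight patients, outcome exactly equal to predictor a."""
    table = pd.DataFrame(
        {
            "a": [1, 1, 1, 0, 0, 0, 0, 0],
            "b": [1, 0, 1, 0, 1, 0, 1, 0],
        },
        dtype=float,
    )
    return Cohort(table, pd.Series([1, 1, 1, 0, 0, 0, 0, 0]), site="tiny")


def random_binary_cohort(rng, n=40, p=5, signal=None):
    """Random binary table; optional dict of per-column outcome log-odds."""
    table = pd.DataFrame(
        {f"x{i}": rng.integers(0, 2, size=n).astype(float) for i in range(p)}
    )
    if signal is None:
        y = rng.integers(0, 2, size=n)
    else:
        logit = -1.0 + sum(w * table[c].to_numpy() for c, w in signal.items())
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    return Cohort(table, pd.Series(y), site="random")
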