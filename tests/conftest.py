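import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from matchdid.panel import Panel

settings.register_profile("suite", deadline=None, max_examples=30,
                          derandomize=True)
settings.load_profile("suite")


def random_panel(rng, n_units=None, n_waves=None, p_missing_row=0.1,
                 p_missing_emp=0.05, p_missing_out=0.05, with_covariates=True):
    """A small random panel for oracle comparisons: arbitrary employment
    paths, integer outcomes, occasional missingness of rows and fields."""
    n_units = n_units or int(rng.integers(5, 31))
    n_waves = n_waves or int(rng.integers(4, 7))
    years = tuple(2006 + 2 * w for w in range(n_waves))
    rows = []
    for i in range(n_units):
        for w, y in enumerate(years):
            if rng.uniform() < p_missing_row:
                continue
            emp = np.nan if rng.uniform() < p_missing_emp else float(rng.integers(0, 2))
            out = np.nan if rng.uniform() < p_missing_out else float(rng.integers(10, 31))
            row = {"unit": f"u{i:03d}", "year": y, "employed": emp,
                   "outcome": out}
            if with_covariates:
                row["age"] = 60.0 + i + w
                row["x1"] = float(rng.normal())
                row["x2"] = float(rng.normal())
            rows.append(row)
    # guarantee at least one record
    if not rows:
        rows.append({"unit": "u000", "year": years[0], "employed": 0.0,
                     "outcome": 25.0, "age": 60.0, "x1": 0.0, "x2": 0.0})
    return Panel(pd.DataFrame(rows), years, (0, 30))


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def tiny_panel():
    """Three units, five waves, fully observed; hand-checkable transitions."""
    years = (2006, 2008, 2010, 2012, 2014)
    rows = []
    emp = {"A": [0, 0, 0, 1, 1], "B": [0, 0, 0, 0, 0], "C": [1, 1, 0, 0, 1]}
    out = {"A": [25, 25, 24, 27, 26], "B": [23, 23, 22, 23, 22],
           "C": [28, 27, 27, 26, 27]}
    for u in emp:
        for w, y in enumerate(years):
            rows.append({"unit": u, "year": y, "employed": emp[u][w],
                         "outcome": out[u][w], "age": 64.0 + w * 2,
                         "x1": float(w), "x2": {"A": 1.0, "B": 0.0,
                                                "C": 2.0}[u]})
    return Panel(pd.DataFrame(rows), years, (0, 30))
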