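import numpy as np
import pandas as pd
import pytest

from lexisurv.rates import LexisPosition, RateTable


def make_table(fill, ages=(0, 100), years=(1966, 2007), sexes=("male", "female"), **kw):
    """A rate table filled from a scalar or an (age, year) -> rate callable."""
    a = np.arange(ages[0], ages[1] + 1)
    y = np.arange(years[0], years[1] + 1)
    if callable(fill):
        grid = fill(a[:, None].astype(float), y[None, :].astype(float)) * np.ones((len(a), len(y)))
    else:
        grid = np.full((len(a), len(y)), float(fill))
    return RateTable({s: grid.copy() for s in sexes}, a, y, **kw)


@pytest.fixture
def const_table():
    """Constant hazard 0.01/yr everywhere."""
    return make_table(0.01)


@pytest.fixture
def piecewise_table():
    """0.01/yr below age 50, 0.02/yr from age 50, all years."""
    return make_table(lambda a, y: np.where(a >= 50, 0.02, 0.01))


@pytest.fixture
def random_table():
    """Distinct positive rate in every (age, year) cell, seeded."""
    rng = np.random.default_rng(20240917)
    a = np.arange(0, 101)
    y = np.arange(1966, 2008)
    return RateTable(
        {
            "male": rng.uniform(0.002, 0.05, size=(len(a), len(y))),
            "female": rng.uniform(0.002, 0.05, size=(len(a), len(y))),
        },
        a,
        y,
    )


@pytest.fixture
def toy_cohort():
    """Ten subjects spanning every sex x smoking-grade cell."""
    grades = ["never", "light", "medium", "heavy", "former"]
    rows = []
    for i, g in enumerate(grades):
        for j, s in enumerate(("male", "female")):
            rows.append(
                {
                    "id": 2 * i + j,
                    "sex": s,
                    "entry_age": 40.0 + i,
                    "entry_year": 1967.0,
                    "followup_years": 10.0 + i + j,
                    "status": "death" if (i + j) % 2 == 0 else "censored",
                    "cause": "all" if (i + j) % 2 == 0 else None,
                    "smoking_grade": g,
                    "byssinosis": (i + j) % 2,
                    "cough_phlegm": i % 2,
                    "years_in_industry": 5.0 + 3 * i,
                    "fev1_pct_pred": 80.0 + 2 * i,
                    "fev1": 2.0 + 0.1 * i,
                    "fvc": 3.0 + 0.1 * i,
                    "height_cm": 160.0 + i + 5 * (1 - j),
                }
            )
    return pd.DataFrame(rows)


def pos(sex="male", age=40.0, year=1970.0):
    return LexisPosition(sex, age, year)
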