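"""Covariate encodings and the gender x smoking-grade design matrix.

The analysis model carries eleven baseline variables: smoking grade (never /
light 1-14 / medium 15-24 / heavy >=25 cigarettes per day / former), a
female indicator, four (or three) female-by-grade interaction indicators
whose exponentiated coefficients are the female-to-male relative risk
ratios (RRRs), and the confounders byssinosis, cough & phlegm, decades
worked in the industry, and two lung-function deficits scaled so a fitted
hazard ratio reads "per 10% reduction".

The 4-RRR scheme forms one interaction per smoking grade; the 3-RRR scheme
pools medium and heavy smokers into a single grade before forming the
interactions (used for cause-specific analyses where deaths are fewer).
Main-effect grade columns are unchanged between schemes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "GRADES",
    "grade_from_cpd",
    "lung_covariates",
    "build_design",
]

#: smoking grades, reference category first
GRADES = ("never", "light", "medium", "heavy", "former")

#: daily-consumption band edges: 1-14 light, 15-24 medium, >=25 heavy
_LIGHT_MAX = 14
_MEDIUM_MAX = 24


def grade_from_cpd(cpd, former: bool = False) -> str:
    """Smoking grade from reported cigarettes per day at baseline.

    A set ``former`` flag overrides consumption (former smokers reported
    zero current consumption).
    """
    if former:
        return "former"
    cpd = int(cpd)
    if cpd < 0:
        raise ValidationError(f"cigarettes per day must be >= 0, got {cpd}")
    if cpd == 0:
        return "never"
    if cpd <= _LIGHT_MAX:
        return "light"
    if cpd <= _MEDIUM_MAX:
        return "medium"
    return "heavy"


def lung_covariates(fev1_pct_pred, fev1, fvc, ratio_sign: str = "interpretation"):
    """The two lung-function covariates on the per-10%-decrease scale.

    Returns ``(fev1_deficit, ratio_deficit)`` where

    * ``fev1_deficit = (100 - FEV1 % predicted) / 10`` — 0 at fully normal
      lung function, +1 when FEV1 is 90% of predicted;
    * ``ratio_deficit`` scores the FEV1/FVC ratio the same way.  With the
      default ``ratio_sign="interpretation"`` it is
      ``(100 - 100 * FEV1/FVC) / 10`` so that a ratio of 0.9 scores +1 and
      the fitted hazard ratio reads "per 10% reduction in the ratio"; the
      alternative ``ratio_sign="printed"`` flips the sign
      (``(100 * FEV1/FVC - 100) / 10``).

    Inputs may be scalars or aligned arrays.
    """
    if ratio_sign not in ("interpretation", "printed"):
        raise ValidationError(f"unknown ratio_sign {ratio_sign!r}")
    fev1_pct_pred = np.asarray(fev1_pct_pred, dtype=float)
    fev1 = np.asarray(fev1, dtype=float)
    fvc = np.asarray(fvc, dtype=float)
    if np.any(fvc <= 0) or np.any(fev1 <= 0) or np.any(fev1_pct_pred <= 0):
        raise ValidationError("lung-function inputs must be positive")
    # small margin above 1 allows for measurement noise in FEV1 vs FVC
    if np.any(fev1 > 1.1 * fvc):
        raise ValidationError("FEV1 exceeds 110% of FVC; inputs look swapped")
    fev1_deficit = (100.0 - fev1_pct_pred) / 10.0
    ratio_deficit = (100.0 - 100.0 * fev1 / fvc) / 10.0
    if ratio_sign == "printed":
        ratio_deficit = -ratio_deficit
    return fev1_deficit[()], ratio_deficit[()]


_CONFOUNDER_SETS = {
    "full": ("byssinosis", "cough_phlegm", "decades_industry",
             "fev1_deficit", "ratio_deficit"),
    "no_lung": ("byssinosis", "cough_phlegm", "decades_industry"),
    "none": (),
}


def _grade_series(cohort: pd.DataFrame) -> pd.Series:
    if "smoking_grade" in cohort.columns:
        g = cohort["smoking_grade"].astype(str)
    elif "smoking_cpd" in cohort.columns:
        former = cohort.get("former_smoker", pd.Series(False, index=cohort.index))
        g = pd.Series(
            [grade_from_cpd(c, bool(f)) for c, f in zip(cohort["smoking_cpd"], former)],
            index=cohort.index,
        )
    else:
        raise ValidationError("cohort needs a smoking_grade or smoking_cpd column")
    bad = set(g.unique()) - set(GRADES)
    if bad:
        raise ValidationError(f"unknown smoking grades: {sorted(bad)}")
    return g


def build_design(
    cohort: pd.DataFrame,
    scheme: str = "rrr4",
    confounders: str = "full",
    log_height: bool = False,
    ratio_sign: str = "interpretation",
) -> pd.DataFrame:
    """Build the named design matrix for the survival regressions.

    Parameters
    ----------
    cohort : DataFrame
        One row per subject with ``sex``, a smoking grade (or consumption)
        column, and whichever confounder columns the chosen set needs
        (``byssinosis``, ``cough_phlegm``, ``years_in_industry``,
        ``fev1_pct_pred``, ``fev1``, ``fvc``, ``height_cm``).
    scheme : {"rrr4", "rrr3"}
        Four female-by-grade interactions, or three with medium and heavy
        pooled.
    confounders : {"full", "no_lung", "none"}
        Which confounder block to include.
    log_height : bool
        Append log(height) as an allometric size covariate.
    ratio_sign : {"interpretation", "printed"}
        Sign convention for the FEV1/FVC covariate (see
        :func:`lung_covariates`).

    Returns a DataFrame indexed like ``cohort`` whose interaction columns
    are exact products of their parent columns.  An unoccupied interaction
    cell (e.g. no female heavy smokers) triggers a warning naming the
    non-estimable RRR.
    """
    if scheme not in ("rrr4", "rrr3"):
        raise ValidationError(f"unknown scheme {scheme!r}")
    if confounders not in _CONFOUNDER_SETS:
        raise ValidationError(f"unknown confounder set {confounders!r}")
    if "sex" not in cohort.columns:
        raise ValidationError("cohort needs a sex column")

    grade = _grade_series(cohort)
    sex = cohort["sex"].astype(str).str.lower()
    bad_sex = set(sex.unique()) - {"male", "female"}
    if bad_sex:
        raise ValidationError(f"unknown sex labels: {sorted(bad_sex)}")
    female = (sex == "female").astype(float)

    X = pd.DataFrame(index=cohort.index)
    for g in GRADES[1:]:
        X[f"grade_{g}"] = (grade == g).astype(float)
    X["female"] = female

    if scheme == "rrr4":
        inter_groups = {"light": ("light",), "medium": ("medium",),
                        "heavy": ("heavy",), "former": ("former",)}
    else:
        inter_groups = {"light": ("light",), "medheavy": ("medium", "heavy"),
                        "former": ("former",)}
    for name, members in inter_groups.items():
        parent = sum((X[f"grade_{g}"] for g in members), start=pd.Series(0.0, index=X.index))
        col = female * parent
        X[f"fem_x_{name}"] = col
        if col.sum() == 0 or (parent * (1 - female)).sum() == 0:
            warnings.warn(
                f"RRR for {name!r} smoking is not estimable: an interaction "
                "cell (female or male) is empty",
                stacklevel=2,
            )

    wanted = _CONFOUNDER_SETS[confounders]
    if "byssinosis" in wanted:
        _need(cohort, "byssinosis")
        X["byssinosis"] = _indicator(cohort["byssinosis"], "byssinosis")
    if "cough_phlegm" in wanted:
        _need(cohort, "cough_phlegm")
        X["cough_phlegm"] = _indicator(cohort["cough_phlegm"], "cough_phlegm")
    if "decades_industry" in wanted:
        _need(cohort, "years_in_industry")
        X["decades_industry"] = cohort["years_in_industry"].astype(float) / 10.0
    if "fev1_deficit" in wanted:
        for c in ("fev1_pct_pred", "fev1", "fvc"):
            _need(cohort, c)
        fd, rd = lung_covariates(
            cohort["fev1_pct_pred"].to_numpy(float),
            cohort["fev1"].to_numpy(float),
            cohort["fvc"].to_numpy(float),
            ratio_sign=ratio_sign,
        )
        X["fev1_deficit"] = fd
        X["ratio_deficit"] = rd
    if log_height:
        _need(cohort, "height_cm")
        h = cohort["height_cm"].astype(float)
        if (h <= 0).any():
            raise ValidationError("heights must be positive")
        X["log_height"] = np.log(h)
    return X


def _need(cohort, col):
    if col not in cohort.columns:
        raise ValidationError(f"cohort lacks required column {col!r}")


def _indicator(series, name):
    vals = series.astype(float)
    if not vals.isin([0.0, 1.0]).all():
        raise ValidationError(f"{name} must be coded 0/1")
    return vals
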