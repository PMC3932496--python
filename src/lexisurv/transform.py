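"""Individual relative-survival transformation of cohort follow-up.

Each subject's observed follow-up time ``t_obs`` is mapped through the
reference-population hazard integrated along their own Lexis diagonal
(their sex, exact age at entry and calendar date at entry):

    Z = Lambda*(t_obs)          the expected cumulative hazard at exit
    Y = 1 - exp(-Z) = 1 - S*(t_obs)

``Y`` is the individual relative-survival measure in [0, 1); ``Z`` is the
alternative measure on [0, inf) with ``Z = -log(1 - Y)``.  Under the null
hypothesis that subjects die exactly like the reference population, ``Z``
is a unit-exponential variate and ``Y`` is uniform, which is what makes the
transformed times comparable across subjects who entered at very different
ages and in different calendar eras.

The transformation carries an event indicator: 1 for the death type under
analysis (all deaths, or deaths from one cause group with deaths from other
causes treated as censored at the death time), 0 otherwise.  Follow-up
beyond attained age 90 is truncated at the 90th birthday with the event
indicator cleared, mirroring an under-90 analysis frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import LexisurvError, ValidationError
from .rates import LexisPosition, RateTable

__all__ = [
    "Subject",
    "TransformedRecord",
    "transform_subject",
    "transform_cohort",
    "RelativeSurvivalTransformer",
    "subjects_from_frame",
]

#: exit-status labels accepted in cohort data
STATUSES = ("death", "censored", "embarked")

#: attained age at which the analysis frame truncates follow-up
AGE_CEILING = 90.0


@dataclass(frozen=True)
class Subject:
    """One cohort member's follow-up record.

    ``entry`` is the Lexis position at first medical examination; follow-up
    runs from there to exit.  ``cause`` must be present iff the status is a
    death.  ``covariates`` holds the baseline covariate bundle (smoking
    grade, lung function, ...) and is opaque to the transformation.
    """

    id: object
    entry: LexisPosition
    followup: float
    status: str
    cause: Optional[str] = None
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (self.followup > 0 and math.isfinite(self.followup)):
            raise ValidationError(
                f"subject {self.id!r}: follow-up must be finite and > 0, "
                f"got {self.followup}"
            )
        if self.status not in STATUSES:
            raise ValidationError(
                f"subject {self.id!r}: unknown exit status {self.status!r} "
                f"(expected one of {STATUSES})"
            )
        if (self.status == "death") != (self.cause is not None):
            raise ValidationError(
                f"subject {self.id!r}: cause of death must be present iff "
                f"status is 'death' (status={self.status!r}, cause={self.cause!r})"
            )


@dataclass(frozen=True)
class TransformedRecord:
    """A subject's transformed follow-up: measures Y and Z plus event flag."""

    id: object
    y: float
    z: float
    event: int

    def __post_init__(self):
        if not 0.0 <= self.y < 1.0:
            raise ValidationError(f"Y must lie in [0, 1), got {self.y}")
        if abs(self.z - (-math.log1p(-self.y))) > 1e-12 * max(1.0, self.z):
            raise ValidationError("Z and -log(1-Y) disagree")
        if self.event not in (0, 1):
            raise ValidationError("event must be 0 or 1")


def _effective_exit(subject: Subject, apply_age90_rule: bool):
    """(follow-up, truncated?) after the attained-age-90 rule."""
    if not apply_age90_rule:
        return subject.followup, False
    room = AGE_CEILING - subject.entry.age
    if room <= 0:
        raise ValidationError(
            f"subject {subject.id!r} entered at age {subject.entry.age:.2f}, "
            f"at or above the age-{AGE_CEILING:g} analysis ceiling"
        )
    if subject.followup > room:
        return room, True
    return subject.followup, False


def transform_subject(
    subject: Subject,
    table: RateTable,
    cause: str = "all",
    apply_age90_rule: bool = True,
) -> TransformedRecord:
    """Transform one subject's follow-up into the (Y, Z, event) record.

    ``cause`` selects the analysis: ``"all"`` scores any death as an event;
    any other label scores only deaths from that cause, censoring deaths
    from other causes at the death time.  ``table`` should be the rate
    table of the same cause group.
    """
    t, truncated = _effective_exit(subject, apply_age90_rule)
    try:
        z = table.cumulative_hazard(subject.entry, t)
    except LexisurvError as exc:
        raise type(exc)(f"subject {subject.id!r}: {exc}") from exc
    event = int(
        (not truncated)
        and subject.status == "death"
        and (cause == "all" or subject.cause == cause)
    )
    y = -math.expm1(-z)
    return TransformedRecord(id=subject.id, y=y, z=z, event=event)


def transform_cohort(
    subjects: Iterable[Subject],
    table: RateTable,
    cause: str = "all",
    apply_age90_rule: bool = True,
):
    """Transform a whole cohort.

    Returns ``(records, summary)`` where ``records`` is a DataFrame with
    columns ``id, y, z, event`` (one row per subject) and ``summary`` is a
    follow-up accounting dict whose categories partition the cohort:
    ``died_before_90``, ``embarked_before_90``, ``censored_at_90`` (exits
    after the 90th birthday, whatever happened later), and
    ``alive_under_90``.
    """
    subjects = list(subjects)
    if not subjects:
        raise ValidationError("cohort is empty")
    ids = [s.id for s in subjects]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate subject ids: {dupes[:5]}")

    rows = []
    summary = {
        "n": len(subjects),
        "died_before_90": 0,
        "embarked_before_90": 0,
        "censored_at_90": 0,
        "alive_under_90": 0,
    }
    for s in subjects:
        rec = transform_subject(s, table, cause=cause, apply_age90_rule=apply_age90_rule)
        rows.append((rec.id, rec.y, rec.z, rec.event))
        _, truncated = _effective_exit(s, apply_age90_rule)
        if truncated:
            summary["censored_at_90"] += 1
        elif s.status == "death":
            summary["died_before_90"] += 1
        elif s.status == "embarked":
            summary["embarked_before_90"] += 1
        else:
            summary["alive_under_90"] += 1
    records = pd.DataFrame(rows, columns=["id", "y", "z", "event"])
    return records, summary


def subjects_from_frame(frame: pd.DataFrame) -> list:
    """Build :class:`Subject` objects from a cohort DataFrame.

    Expects columns ``id, sex, entry_age, entry_year, followup_years,
    status`` and optionally ``cause``; all remaining columns are carried in
    ``covariates``.  Integer entry ages are taken as mid-year ages
    (``age + 0.5``), the unbiased choice under uniformly distributed
    birthdays.
    """
    required = {"id", "sex", "entry_age", "entry_year", "followup_years", "status"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"cohort frame lacks columns: {sorted(missing)}")
    ages = frame["entry_age"].to_numpy(dtype=float)
    if pd.api.types.is_integer_dtype(frame["entry_age"]):
        ages = ages + 0.5
    extra = [c for c in frame.columns if c not in required | {"cause"}]
    out = []
    for k, (_, row) in enumerate(frame.iterrows()):
        cause = row.get("cause")
        if isinstance(cause, float) and math.isnan(cause):
            cause = None
        out.append(
            Subject(
                id=row["id"],
                entry=LexisPosition(str(row["sex"]), float(ages[k]), float(row["entry_year"])),
                followup=float(row["followup_years"]),
                status=str(row["status"]),
                cause=cause,
                covariates={c: row[c] for c in extra},
            )
        )
    return out


class RelativeSurvivalTransformer(BaseEstimator, TransformerMixin):
    """Scikit-learn style transformer wrapping :func:`transform_cohort`.

    Parameters
    ----------
    rate_table : RateTable
        Reference mortality rates (matching the analysis cause).
    cause : str
        ``"all"`` or a cause-of-death label.
    apply_age90_rule : bool
        Truncate follow-up at attained age 90 (default True).

    ``transform`` accepts either a cohort DataFrame (see
    :func:`subjects_from_frame`) or an iterable of :class:`Subject` and
    returns the ``(id, y, z, event)`` DataFrame.  The follow-up accounting
    of the last transform is exposed as ``summary_``.
    """

    def __init__(self, rate_table=None, cause="all", apply_age90_rule=True):
        self.rate_table = rate_table
        self.cause = cause
        self.apply_age90_rule = apply_age90_rule

    def fit(self, X=None, y=None):
        if self.rate_table is None:
            raise ValidationError("rate_table must be set before use")
        if not isinstance(self.rate_table, RateTable):
            raise ValidationError("rate_table must be a RateTable")
        return self

    def transform(self, X):
        self.fit()
        subjects = subjects_from_frame(X) if isinstance(X, pd.DataFrame) else X
        records, summary = transform_cohort(
            subjects,
            self.rate_table,
            cause=self.cause,
            apply_age90_rule=self.apply_age90_rule,
        )
        self.summary_ = summary
        return records
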