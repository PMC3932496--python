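"""Delimited-text cohort files.

One row per subject; required columns ``id, sex, entry_age, entry_year,
followup_years, status`` plus whatever baseline covariates the design
needs.  A ``column_map`` renames file headers onto these canonical names,
so arbitrary source layouts can be read without editing the file.
"""

from __future__ import annotations

import pandas as pd

from .errors import ValidationError

__all__ = ["read_cohort", "write_cohort", "REQUIRED_COLUMNS"]

REQUIRED_COLUMNS = ("id", "sex", "entry_age", "entry_year", "followup_years", "status")


def read_cohort(path, column_map: dict | None = None, sep=",") -> pd.DataFrame:
    """Read a cohort table, validating the required columns.

    ``column_map`` maps file header names to canonical names, e.g.
    ``{"dob_age": "entry_age"}``.  Integer entry ages are interpreted
    downstream as mid-year ages (age + 0.5).
    """
    try:
        frame = pd.read_csv(path, sep=sep)
    except FileNotFoundError:
        raise ValidationError(f"cohort file not found: {path}") from None
    except pd.errors.ParserError as exc:
        raise ValidationError(f"cannot parse cohort file {path}: {exc}") from None
    if column_map:
        frame = frame.rename(columns=column_map)
    missing = set(REQUIRED_COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError(
            f"cohort file {path} lacks required columns: {sorted(missing)}"
        )
    if frame["id"].duplicated().any():
        dupes = frame.loc[frame["id"].duplicated(), "id"].head().tolist()
        raise ValidationError(f"cohort file {path} has duplicate ids: {dupes}")
    return frame


def write_cohort(frame: pd.DataFrame, path, sep=",") -> None:
    """Write a cohort table in the canonical delimited layout."""
    frame.to_csv(path, sep=sep, index=False)
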