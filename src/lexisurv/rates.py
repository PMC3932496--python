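"""Reference population mortality rates on the age x calendar-year plane.

A :class:`RateTable` holds sex-specific central mortality rates (deaths per
person-year) on a rectangular grid of single years of age by single calendar
years.  A cohort member entering at exact age ``a0`` in decimal year ``y0``
moves along the 45-degree diagonal of the Lexis plane: after ``s`` years of
follow-up they are aged ``a0 + s`` in year ``y0 + s``.  The hazard is taken
as piecewise constant within each 1-year x 1-year cell, so the expected
cumulative hazard

    Lambda*(t) = integral_0^t  mu(sex, a0 + s, y0 + s) ds

is piecewise linear in ``t`` with knots wherever the diagonal crosses an
integer age (the subject's fractional birthday) or an integer calendar year.
The integral is evaluated exactly by splitting the diagonal at both kinds of
boundary.  ``Z = Lambda*(t_obs)`` is the transformed survival time used by
the individual relative-survival analysis; if a subject dies exactly like
the reference population, ``Z`` is a unit-exponential variate.

Extrapolation beyond the grid is explicit and configurable: calendar years
outside ``[first_year, last_year]`` reuse the nearest column, and ages above
``max_age`` are extended log-linearly (a Gompertz tail fitted to the top
ages of the grid), capped at a configurable hazard.  Queries outside the
grid with extrapolation disabled raise :class:`~lexisurv.errors.RateRangeError`
naming the missing cell.

Dates are decimal years throughout (365.25-day year); no calendar-exact date
arithmetic is attempted.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import RateRangeError, SaturationError, ValidationError

__all__ = [
    "LexisPosition",
    "RateTable",
    "cumulative_hazard",
    "expected_survival",
    "invert_cumulative_hazard",
    "read_rate_table",
    "write_rate_table",
]


@dataclass(frozen=True)
class LexisPosition:
    """A starting point on the Lexis plane.

    Parameters
    ----------
    sex : str
        ``"male"`` or ``"female"`` (any label present in the rate table).
    age : float
        Exact age at entry in years; fractional values allowed.
    year : float
        Calendar date at entry in decimal years (e.g. ``1966.5``).
    """

    sex: str
    age: float
    year: float

    def __post_init__(self):
        if not (self.age >= 0 and math.isfinite(self.age)):
            raise ValidationError(f"entry age must be finite and >= 0, got {self.age}")
        if not math.isfinite(self.year):
            raise ValidationError(f"entry year must be finite, got {self.year}")

    def advanced(self, dt: float) -> "LexisPosition":
        """The position ``dt`` years later along the Lexis diagonal."""
        return LexisPosition(self.sex, self.age + dt, self.year + dt)


@dataclass
class RateTable:
    """Sex-specific mortality rates on an age x calendar-year grid.

    Parameters
    ----------
    rates : dict of str -> ndarray
        One matrix per sex, shape ``(n_ages, n_years)``, deaths per
        person-year.
    ages, years : array-like of int
        Row / column labels; both must be strictly increasing with unit step.
    cause : str
        Cause-of-death label (``"all"`` for all-cause tables).
    extrapolate : bool
        If False, any query off the grid raises ``RateRangeError``.
    age_cap : int
        Highest attained age the Gompertz extension reaches; beyond it no
        hazard exists and inversion saturates.
    hazard_cap : float
        Ceiling (per year) applied to extrapolated old-age hazards.
    gompertz_ages : int
        Number of top grid ages used to fit the log-linear age extension.
    """

    rates: dict
    ages: np.ndarray
    years: np.ndarray
    cause: str = "all"
    extrapolate: bool = True
    age_cap: int = 130
    hazard_cap: float = 1.0
    gompertz_ages: int = 10
    _ext: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=int)
        self.years = np.asarray(self.years, dtype=int)
        if self.ages.ndim != 1 or self.years.ndim != 1:
            raise ValidationError("age and year axes must be 1-D")
        if len(self.ages) == 0 or len(self.years) == 0:
            raise ValidationError("rate table axes must be non-empty")
        if not np.all(np.diff(self.ages) == 1):
            raise ValidationError("age axis must be strictly increasing with unit step")
        if not np.all(np.diff(self.years) == 1):
            raise ValidationError("year axis must be strictly increasing with unit step")
        if not self.rates:
            raise ValidationError("rate table must cover at least one sex")
        clean = {}
        for sex, grid in self.rates.items():
            grid = np.asarray(grid, dtype=float)
            if grid.shape != (len(self.ages), len(self.years)):
                raise ValidationError(
                    f"rate matrix for sex={sex!r} has shape {grid.shape}, "
                    f"expected {(len(self.ages), len(self.years))}"
                )
            if not np.all(np.isfinite(grid)) or np.any(grid < 0):
                raise ValidationError(
                    f"rates for sex={sex!r} must all be finite and >= 0"
                )
            clean[sex] = grid
        self.rates = clean
        if self.age_cap <= self.max_age:
            raise ValidationError("age_cap must exceed the top grid age")
        self._ext = {}

    # -- basic geometry -----------------------------------------------------

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    @property
    def first_year(self) -> int:
        return int(self.years[0])

    @property
    def last_year(self) -> int:
        return int(self.years[-1])

    @property
    def sexes(self):
        return tuple(self.rates)

    def with_policy(self, **kw) -> "RateTable":
        """A copy with a different extrapolation policy."""
        return replace(self, _ext={}, **kw)

    # -- extrapolated grid --------------------------------------------------

    def _extended(self, sex: str) -> np.ndarray:
        """Rate matrix for ages ``min_age .. age_cap`` (Gompertz tail above
        the grid, capped at ``hazard_cap``).  Cached per sex."""
        if sex not in self.rates:
            raise ValidationError(
                f"sex {sex!r} not in rate table (has {sorted(self.rates)})"
            )
        cached = self._ext.get(sex)
        if cached is not None:
            return cached
        grid = self.rates[sex]
        n_extra = self.age_cap - self.max_age
        m = min(self.gompertz_ages, len(self.ages))
        top_ages = self.ages[-m:].astype(float)
        top = grid[-m:, :]
        with np.errstate(divide="ignore"):
            logtop = np.log(top)
        ext_ages = np.arange(self.max_age + 1, self.age_cap + 1, dtype=float)
        cols = []
        for j in range(grid.shape[1]):
            lj = logtop[:, j]
            ok = np.isfinite(lj)
            if ok.sum() >= 2:
                slope, intercept = np.polyfit(top_ages[ok], lj[ok], 1)
                tail = np.exp(intercept + slope * ext_ages)
            else:  # degenerate column (zero rates): carry the last rate
                tail = np.full(n_extra, grid[-1, j])
            cols.append(np.minimum(tail, self.hazard_cap))
        ext = np.vstack([grid, np.column_stack(cols)])
        self._ext[sex] = ext
        return ext

    def rate_at(self, sex: str, age: int, year: int) -> float:
        """The hazard in one Lexis cell, honouring the extrapolation policy."""
        age = int(math.floor(age))
        year = int(math.floor(year))
        in_age = self.min_age <= age <= self.max_age
        in_year = self.first_year <= year <= self.last_year
        if not self.extrapolate and not (in_age and in_year):
            raise RateRangeError(sex, age, year)
        if age > self.age_cap:
            raise SaturationError(
                f"attained age {age} exceeds the extrapolation ceiling "
                f"({self.age_cap}) for sex={sex!r}"
            )
        j = int(np.clip(year - self.first_year, 0, len(self.years) - 1))
        grid = self._extended(sex) if self.extrapolate else self.rates[sex]
        i = age - self.min_age
        if i < 0:
            raise RateRangeError(
                sex, age, year, f"age {age} below the table floor ({self.min_age})"
            )
        return float(grid[i, j])

    # -- Lexis path ---------------------------------------------------------

    def _path(self, pos: LexisPosition, horizon: float):
        """Knots and cumulative hazard along the Lexis diagonal.

        Returns ``(breaks, cum)`` with ``breaks[0] == 0``,
        ``breaks[-1] == horizon`` and ``cum`` the exact piecewise-linear
        cumulative hazard at each knot.
        """
        a0, y0 = float(pos.age), float(pos.year)
        if horizon < 0:
            raise ValidationError(f"follow-up must be >= 0, got {horizon}")
        if horizon == 0:
            return np.array([0.0]), np.array([0.0])
        age_knots = np.arange(math.floor(a0) + 1.0, a0 + horizon) - a0
        year_knots = np.arange(math.floor(y0) + 1.0, y0 + horizon) - y0
        breaks = np.unique(np.concatenate(
            [[0.0, horizon], age_knots, year_knots]
        ))
        breaks = breaks[(breaks >= 0.0) & (breaks <= horizon)]
        mid = 0.5 * (breaks[:-1] + breaks[1:])
        cell_age = np.floor(a0 + mid).astype(int)
        cell_year = np.floor(y0 + mid).astype(int)

        if pos.sex not in self.rates:
            raise ValidationError(
                f"sex {pos.sex!r} not in rate table (has {sorted(self.rates)})"
            )
        if not self.extrapolate:
            bad = (
                (cell_age < self.min_age) | (cell_age > self.max_age)
                | (cell_year < self.first_year) | (cell_year > self.last_year)
            )
            if bad.any():
                k = int(np.argmax(bad))
                raise RateRangeError(pos.sex, int(cell_age[k]), int(cell_year[k]))
            grid = self.rates[pos.sex]
            top = self.max_age
        else:
            grid = self._extended(pos.sex)
            top = self.age_cap
            if cell_age[-1] > top:
                raise SaturationError(
                    f"follow-up {horizon:.3f}y from age {a0:.3f} exceeds the "
                    f"extrapolation ceiling (attained age > {top})"
                )
        if cell_age[0] < self.min_age:
            raise RateRangeError(
                pos.sex, int(cell_age[0]), int(cell_year[0]),
                f"age {cell_age[0]} below the table floor ({self.min_age})",
            )
        i = cell_age - self.min_age
        j = np.clip(cell_year - self.first_year, 0, len(self.years) - 1)
        seg_rates = grid[i, j]
        cum = np.concatenate([[0.0], np.cumsum(seg_rates * np.diff(breaks))])
        return breaks, cum

    def max_horizon(self, pos: LexisPosition) -> float:
        """Longest follow-up representable before the age ceiling."""
        top = self.age_cap if self.extrapolate else (self.max_age + 1)
        return max(0.0, float(top) - float(pos.age))

    # -- public queries -----------------------------------------------------

    def cumulative_hazard(self, pos: LexisPosition, t):
        """Expected cumulative hazard Lambda*(t) along the Lexis diagonal.

        ``t`` may be a scalar or an array of follow-up times (years).
        """
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t_arr < 0) or not np.all(np.isfinite(t_arr)):
            raise ValidationError("follow-up times must be finite and >= 0")
        tmax = float(t_arr.max(initial=0.0))
        breaks, cum = self._path(pos, tmax)
        out = np.interp(t_arr, breaks, cum)
        return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out

    def expected_survival(self, pos: LexisPosition, t):
        """Expected survival S*(t) = exp(-Lambda*(t))."""
        return np.exp(-np.asarray(self.cumulative_hazard(pos, t)))[()]

    def invert_cumulative_hazard(self, pos: LexisPosition, z):
        """Follow-up time t with Lambda*(t) = z (scalar or array ``z``).

        Raises :class:`SaturationError` if ``z`` exceeds the cumulative
        hazard attainable at the table ceiling.
        """
        z_arr = np.atleast_1d(np.asarray(z, dtype=float))
        if np.any(z_arr < 0) or not np.all(np.isfinite(z_arr)):
            raise ValidationError("target cumulative hazards must be finite and >= 0")
        horizon = self.max_horizon(pos)
        breaks, cum = self._path(pos, horizon)
        zmax = float(z_arr.max(initial=0.0))
        if zmax > cum[-1]:
            raise SaturationError(
                f"target cumulative hazard {zmax:.6g} exceeds the ceiling "
                f"value {cum[-1]:.6g} attainable from age {pos.age:.2f} "
                f"(attained-age cap {self.age_cap if self.extrapolate else self.max_age + 1})"
            )
        out = np.interp(z_arr, cum, breaks)
        return float(out[0]) if np.isscalar(z) or np.ndim(z) == 0 else out


# -- module-level functional API --------------------------------------------

def cumulative_hazard(table: RateTable, pos: LexisPosition, t):
    """Expected cumulative hazard Lambda*(t); see :meth:`RateTable.cumulative_hazard`."""
    return table.cumulative_hazard(pos, t)


def expected_survival(table: RateTable, pos: LexisPosition, t):
    """Expected survival S*(t) = exp(-Lambda*(t))."""
    return table.expected_survival(pos, t)


def invert_cumulative_hazard(table: RateTable, pos: LexisPosition, z):
    """Inverse of the expected cumulative hazard in follow-up time."""
    return table.invert_cumulative_hazard(pos, z)


# -- plain-text persistence --------------------------------------------------
#
# Format: an optional comment header, then one "[sex]" section per sex.  Each
# section is CSV with a header row "age,<year>,<year>,..." and one row per
# single year of age.  All sections must share identical axes.

_SECTION_RE = re.compile(r"^\[([^\]]+)\]\s*$")


def write_rate_table(table: RateTable, path) -> None:
    """Write a rate table in the sectioned delimited-text format."""
    with open(path, "w") as fh:
        fh.write("# lexisurv rate table\n")
        fh.write(f"# cause: {table.cause}\n")
        for sex in table.sexes:
            fh.write(f"[{sex}]\n")
            fh.write("age," + ",".join(str(y) for y in table.years) + "\n")
            for i, age in enumerate(table.ages):
                row = ",".join(format(v, ".17g") for v in table.rates[sex][i])
                fh.write(f"{age},{row}\n")


def read_rate_table(path, **policy) -> RateTable:
    """Read a rate table written by :func:`write_rate_table`.

    Malformed grids (negative rates, gaps in either axis, ragged rows) are
    rejected with a :class:`ValidationError` that cites the offending line.
    Extra keyword arguments set the extrapolation policy.
    """
    cause = "all"
    sections: dict[str, list[tuple[int, str]]] = {}
    current = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.lstrip().startswith("#"):
                m = re.match(r"#\s*cause:\s*(.+)$", line.strip())
                if m:
                    cause = m.group(1).strip()
                continue
            m = _SECTION_RE.match(line.strip())
            if m:
                current = m.group(1).strip()
                if current in sections:
                    raise ValidationError(
                        f"{path}:{lineno}: duplicate section [{current}]"
                    )
                sections[current] = []
                continue
            if current is None:
                raise ValidationError(
                    f"{path}:{lineno}: data before any [sex] section header"
                )
            sections[current].append((lineno, line))

    if not sections:
        raise ValidationError(f"{path}: no [sex] sections found")

    rates = {}
    axes = None
    for sex, rows in sections.items():
        if len(rows) < 2:
            raise ValidationError(f"{path}: section [{sex}] has no data rows")
        header_lineno, header = rows[0]
        cols = [c.strip() for c in header.split(",")]
        if not cols or cols[0].lower() != "age":
            raise ValidationError(
                f"{path}:{header_lineno}: header must start with 'age'"
            )
        try:
            years = np.array([int(c) for c in cols[1:]])
        except ValueError as exc:
            raise ValidationError(
                f"{path}:{header_lineno}: non-integer year column: {exc}"
            ) from None
        if len(years) == 0:
            raise ValidationError(f"{path}:{header_lineno}: no year columns")
        if not np.all(np.diff(years) == 1):
            raise ValidationError(
                f"{path}:{header_lineno}: year columns must be consecutive "
                f"(got {years.tolist()})"
            )
        ages, grid = [], []
        for lineno, line in rows[1:]:
            parts = [p.strip() for p in line.split(",")]
            if len(parts) != len(years) + 1:
                raise ValidationError(
                    f"{path}:{lineno}: expected {len(years) + 1} fields, "
                    f"got {len(parts)}"
                )
            try:
                age = int(parts[0])
                vals = np.array([float(p) for p in parts[1:]])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
            if ages and age != ages[-1] + 1:
                raise ValidationError(
                    f"{path}:{lineno}: age {age} breaks the unit-step axis "
                    f"(previous age {ages[-1]})"
                )
            if np.any(vals < 0) or not np.all(np.isfinite(vals)):
                raise ValidationError(
                    f"{path}:{lineno}: negative or non-finite rate"
                )
            ages.append(age)
            grid.append(vals)
        ages = np.array(ages)
        if axes is None:
            axes = (ages, years)
        elif not (np.array_equal(axes[0], ages) and np.array_equal(axes[1], years)):
            raise ValidationError(
                f"{path}: section [{sex}] axes differ from earlier sections"
            )
        rates[sex] = np.vstack(grid)

    return RateTable(rates=rates, ages=axes[0], years=axes[1], cause=cause, **policy)
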