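"""Exception hierarchy for lexisurv.

All recoverable analysis failures derive from :class:`LexisurvError` so a
driver (CLI or pipeline) can map them onto exit codes: validation problems
(bad files, bad queries) are :class:`ValidationError`, optimiser failures are
:class:`ConvergenceError`.
"""


class LexisurvError(Exception):
    """Base class for all package errors."""


class ValidationError(LexisurvError):
    """Malformed input: files, grids, cohorts or configuration."""


class RateRangeError(ValidationError):
    """A (sex, age, year) cell was queried outside the rate table span
    with extrapolation disabled."""

    def __init__(self, sex, age, year, message=None):
        self.sex = sex
        self.age = age
        self.year = year
        msg = message or (
            f"no mortality rate for sex={sex!r}, age={age}, year={year} "
            "and extrapolation is disabled"
        )
        super().__init__(msg)


class SaturationError(LexisurvError):
    """A target cumulative hazard exceeds the hazard integral attainable at
    the (possibly extrapolated) ceiling of the rate table."""


class ConvergenceError(LexisurvError):
    """An iterative fit failed to converge (monotone likelihood, ill
    conditioning, or iteration budget exhausted)."""
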