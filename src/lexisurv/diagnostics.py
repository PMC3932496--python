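"""Proportional-hazards diagnostics via scaled Schoenfeld residuals.

At each event time the Schoenfeld residual is the covariate vector of the
case minus the risk-set weighted mean covariate under the fitted model;
tied events (Efron fits) use the average of the Efron-adjusted means so
that the residual columns still sum to the score, which is zero at the
maximum partial-likelihood estimate.  The scaled residuals premultiply the
raw ones by (number of events) times the coefficient covariance; a trend
of a scaled-residual column over time estimates how that coefficient
drifts, so a non-zero correlation with time signals non-proportional
hazards.

The test statistic here is the Pearson correlation coefficient rho between
each scaled-residual column and the event times on the transformed
(relative-survival) scale, with a p-value from the t distribution on
(events - 2) degrees of freedom.  The time axis is the identity on Z by
default; a rank transform is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .models import FitResult, _as_matrix, _cox_groups, _unpack_y, _records_to_y

__all__ = ["PHTestResult", "schoenfeld_residuals", "ph_test", "proportional_hazards_test"]


@dataclass
class PHTestResult:
    """Per-covariate correlation test of the PH assumption."""

    table: pd.DataFrame  # columns: rho, p, n_events
    transform: str = "identity"

    def __getitem__(self, name):
        return self.table.loc[name]


def schoenfeld_residuals(fit: FitResult, records: pd.DataFrame, X):
    """Raw and scaled Schoenfeld residuals of a Cox fit.

    Returns ``(raw, scaled)``: DataFrames with one row per event (ordered
    by event time, index = event time on the fit's time scale) and one
    column per covariate.  Raw residual columns sum to zero at the fitted
    coefficients (the score equations); scaled residuals are
    ``n_events * cov(beta) @ raw`` per row.
    """
    if fit.family != "cox":
        raise ValidationError("Schoenfeld residuals require a Cox fit")
    Xm, names = _as_matrix(X)
    event, time = _unpack_y(_records_to_y(records, fit.scale_axis))
    if event.sum() < 2:
        raise ValidationError("at least 2 events are required")
    if names != fit.covariate_names:
        raise ValidationError("design columns do not match the fitted model")
    beta = fit.coef.to_numpy()

    order, groups = _cox_groups(time, event)
    Xs = Xm[order]
    ts = time[order]
    eta = Xs @ beta
    w = np.exp(eta - eta.max())
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w[:, None] * Xs)[::-1], axis=0)[::-1]

    rows, times_out = [], []
    ties = getattr(fit.model, "ties", "efron")
    for start, ev in groups:
        m = len(ev)
        s0, s1 = S0[start], S1[start]
        if ties == "efron" and m > 1:
            frac = np.arange(m) / m
            s0d = w[ev].sum()
            s1d = (w[ev, None] * Xs[ev]).sum(axis=0)
            phi = s0 - frac * s0d
            mean = ((s1[None, :] - frac[:, None] * s1d) / phi[:, None]).mean(axis=0)
        else:
            mean = s1 / s0
        for k in ev:
            rows.append(Xs[k] - mean)
            times_out.append(ts[k])
    raw = pd.DataFrame(rows, columns=names, index=pd.Index(times_out, name="time"))
    V = fit.cov.loc[names, names].to_numpy()
    scaled = pd.DataFrame(
        (len(rows) * (V @ raw.to_numpy().T)).T, columns=names, index=raw.index
    )
    return raw, scaled


def ph_test(scaled: pd.DataFrame, times=None, transform: str = "identity") -> PHTestResult:
    """Correlation test of scaled Schoenfeld residuals against event time.

    ``times`` defaults to the residual index (event times on the
    transformed scale).  ``transform="rank"`` correlates against the ranks
    of the event times instead of the identity axis.  A residual column
    with zero variance yields an undefined rho (NaN) with a warning.
    """
    if transform not in ("identity", "rank"):
        raise ValidationError(f"unknown time transform {transform!r}")
    t = np.asarray(scaled.index if times is None else times, dtype=float)
    if len(t) != len(scaled):
        raise ValidationError("residuals and event times do not conform")
    d = len(t)
    if d < 3:
        raise ValidationError("need at least 3 events for the correlation test")
    if transform == "rank":
        t = stats.rankdata(t)
    tc = t - t.mean()
    st = np.sqrt((tc ** 2).sum())
    out = {}
    for col in scaled.columns:
        r = scaled[col].to_numpy(dtype=float)
        rc = r - r.mean()
        sr = np.sqrt((rc ** 2).sum())
        if sr == 0 or st == 0:
            warnings.warn(
                f"zero-variance scaled residuals for {col!r}; rho undefined",
                stacklevel=2,
            )
            out[col] = (np.nan, np.nan)
            continue
        rho = float((tc * rc).sum() / (st * sr))
        rho = max(-1.0, min(1.0, rho))
        if abs(rho) == 1.0:
            p = 0.0
        else:
            tstat = rho * np.sqrt((d - 2) / (1.0 - rho ** 2))
            p = 2.0 * stats.t.sf(abs(tstat), d - 2)
        out[col] = (rho, p)
    table = pd.DataFrame(out, index=["rho", "p"]).T
    table["n_events"] = d
    return PHTestResult(table=table, transform=transform)


def proportional_hazards_test(
    fit: FitResult, records: pd.DataFrame, X, transform: str = "identity"
) -> PHTestResult:
    """Convenience wrapper: residuals + correlation test in one call."""
    _, scaled = schoenfeld_residuals(fit, records, X)
    return ph_test(scaled, transform=transform)
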