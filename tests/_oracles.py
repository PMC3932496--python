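"""Independent oracles used by the test suite.

Each oracle recomputes a quantity from first principles by a different
route than the library (fine-grid integration, explicit likelihood
enumeration, risk-set loops) so agreement is evidence, not tautology.
"""

import numpy as np
from scipy import optimize


def riemann_cumulative_hazard(table, sex, a0, y0, t, step=1.0 / 3650.0):
    """Fine-grid midpoint integration of the reference hazard along the
    Lexis diagonal, looking rates up directly in the raw grid by floor().

    The uniform grid is augmented with the exact integer-age and
    integer-year crossing times so the midpoint rule is exact for a
    piecewise-constant integrand (up to float rounding).
    """
    if t == 0:
        return 0.0
    pts = np.concatenate([
        np.arange(0.0, t, step),
        [t],
        np.arange(np.floor(a0) + 1.0, a0 + t) - a0,
        np.arange(np.floor(y0) + 1.0, y0 + t) - y0,
    ])
    pts = np.unique(pts[(pts >= 0.0) & (pts <= t)])
    mids = 0.5 * (pts[:-1] + pts[1:])
    ages = np.floor(a0 + mids).astype(int)
    yrs = np.floor(y0 + mids).astype(int)
    grid = table.rates[sex]
    i = ages - int(table.ages[0])
    j = np.clip(yrs - int(table.years[0]), 0, len(table.years) - 1)
    r = grid[i, j]
    return float(np.sum(r * np.diff(pts)))


def cox_partial_loglik_1d(beta, x, time, event):
    """Explicit Cox partial log-likelihood for one covariate, no ties."""
    order = np.argsort(time)
    x, time, event = x[order], time[order], event[order]
    ll = 0.0
    for i in range(len(time)):
        if event[i]:
            risk = time >= time[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def cox_brute_force_1d(x, time, event, lo=-10.0, hi=10.0):
    """Maximise the explicit one-covariate partial likelihood: coarse grid
    scan followed by bounded scalar minimisation to ~1e-8."""
    grid = np.linspace(lo, hi, 401)
    vals = [cox_partial_loglik_1d(b, x, time, event) for b in grid]
    b0 = grid[int(np.argmax(vals))]
    res = optimize.minimize_scalar(
        lambda b: -cox_partial_loglik_1d(b, x, time, event),
        bounds=(max(lo, b0 - 0.5), min(hi, b0 + 0.5)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def schoenfeld_enumeration(beta, X, time, event):
    """From-definition Schoenfeld residuals for untied data: at each event
    time, the case's covariates minus the risk-set weighted mean.

    Returns (event_times, residual matrix) ordered by event time.
    """
    beta = np.asarray(beta, float)
    X = np.asarray(X, float)
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    ev_idx = np.argsort(time)
    out_t, out_r = [], []
    for i in ev_idx:
        if not event[i]:
            continue
        risk = time >= time[i]
        w = np.exp(X[risk] @ beta)
        mean = (w[:, None] * X[risk]).sum(axis=0) / w.sum()
        out_t.append(time[i])
        out_r.append(X[i] - mean)
    return np.array(out_t), np.array(out_r)
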