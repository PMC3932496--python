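"""Proportional-hazards regression on the transformed survival times.

Two estimator families, both scikit-learn ``BaseEstimator`` subclasses that
fit on ``(X, y)`` where ``y`` is a structured array with ``event`` and
``time`` fields (the scikit-survival convention; :func:`survival_array`
builds one):

* :class:`CoxPH` — the semi-parametric Cox model, maximising the partial
  likelihood by Newton-Raphson with step-halving (Efron tie handling by
  default, Breslow selectable).  Because the partial likelihood depends on
  the times only through their ranks, the fit is identical on the ``Y`` and
  ``Z`` relative-survival scales, or under any strictly increasing
  re-expression of time.

* :class:`WeibullPH` — a fully parametric Weibull model in the
  proportional-hazards parameterisation

      h(z | x) = k * lam * z**(k-1) * exp(x @ beta),

  so ``beta`` is directly comparable with the Cox coefficients and reduces
  to the exponential model when the shape ``k`` is fixed at 1.  Fitted by
  Newton-Raphson on (beta, log lam, log k) with analytic gradient and
  Hessian and a quasi-Newton (BFGS) fallback.

Both produce a :class:`FitResult` holding the coefficient vector, the
inverse-information covariance, the log-likelihood (partial for Cox) and a
derived hazard-ratio table with Wald 95% confidence intervals.  Rows whose
name starts with ``fem_x_`` are female-to-male relative risk ratios (RRRs):
the exponentiated gender-by-smoking-grade interaction coefficients.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .errors import ConvergenceError, ValidationError

__all__ = [
    "survival_array",
    "ModelSpec",
    "FitResult",
    "CoxPH",
    "WeibullPH",
    "fit_cox",
    "fit_weibull",
    "extract_rrr",
    "compare_models",
]

_Z975 = 1.959963984540054  # Phi^{-1}(0.975)

RRR_PREFIX = "fem_x_"


def survival_array(event, time) -> np.ndarray:
    """Pack event indicators and times into a structured survival array."""
    event = np.asarray(event)
    time = np.asarray(time, dtype=float)
    if event.shape != time.shape or event.ndim != 1:
        raise ValidationError("event and time must be aligned 1-D arrays")
    out = np.empty(len(event), dtype=[("event", "?"), ("time", "<f8")])
    out["event"] = event.astype(bool)
    out["time"] = time
    return out


def _unpack_y(y):
    """(event bool array, time float array) from the accepted y formats."""
    if isinstance(y, np.ndarray) and y.dtype.names:
        names = set(y.dtype.names)
        if not {"event", "time"} <= names:
            raise ValidationError("structured y needs 'event' and 'time' fields")
        return y["event"].astype(bool), y["time"].astype(float)
    if isinstance(y, pd.DataFrame):
        if not {"event", "time"} <= set(y.columns):
            raise ValidationError("y frame needs 'event' and 'time' columns")
        return y["event"].to_numpy(bool), y["time"].to_numpy(float)
    if isinstance(y, (tuple, list)) and len(y) == 2:
        return np.asarray(y[0], bool), np.asarray(y[1], float)
    raise ValidationError(
        "y must be a structured (event, time) array, a DataFrame with those "
        "columns, or an (event, time) pair"
    )


def _as_matrix(X):
    """(ndarray, column names) from a DataFrame or array."""
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("X must be 2-D")
    return X, [f"x{j}" for j in range(X.shape[1])]


def _check_rank(X, names):
    """Raise naming (nearly) collinear columns if X is rank deficient."""
    if X.shape[1] == 0:
        raise ValidationError("design matrix has no columns")
    r = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(r))
    scale = diag.max() if diag.max() > 0 else 1.0
    bad = [names[j] for j in np.nonzero(diag < 1e-10 * scale)[0]]
    if bad:
        raise ValidationError(f"design matrix is rank deficient; collinear columns: {bad}")


@dataclass(frozen=True)
class ModelSpec:
    """Options shared by the model-fitting wrappers.

    ``scale`` picks which relative-survival measure is the time axis
    (``"z"`` or ``"y"``); the Weibull family requires ``"z"``.
    """

    family: str = "cox"
    scale: str = "z"
    ties: str = "efron"
    tol: float = 1e-9
    max_iter: int = 100

    def __post_init__(self):
        if self.family not in ("cox", "weibull", "exponential"):
            raise ValidationError(f"unknown family {self.family!r}")
        if self.scale not in ("z", "y"):
            raise ValidationError(f"unknown time scale {self.scale!r}")
        if self.ties not in ("efron", "breslow"):
            raise ValidationError(f"unknown tie method {self.ties!r}")
        if not (self.tol > 0 and self.max_iter > 0):
            raise ValidationError("tolerances and iteration budget must be positive")


@dataclass
class FitResult:
    """A fitted proportional-hazards model, with derived summaries."""

    family: str
    params: pd.Series           # beta, plus log_scale / log_shape when parametric
    cov: pd.DataFrame           # inverse observed information
    loglik: float
    n: int
    n_events: int
    scale_axis: str             # "z" or "y"
    covariate_names: list
    shape: Optional[float] = None   # Weibull k
    rate: Optional[float] = None    # Weibull lam (baseline rate)
    data_hash: str = ""
    model: object = field(default=None, repr=False)

    @property
    def coef(self) -> pd.Series:
        return self.params[self.covariate_names]

    @property
    def se(self) -> pd.Series:
        d = np.sqrt(np.diag(self.cov.to_numpy()))
        return pd.Series(d, index=self.params.index)[self.covariate_names]

    @property
    def n_params(self) -> int:
        return len(self.params)

    def summary(self) -> pd.DataFrame:
        """Hazard-ratio table: HR, 95% CI (Wald, log scale), p, RRR flag."""
        beta = self.coef
        se = self.se
        z = beta / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {
                "coef": beta,
                "se": se,
                "hr": np.exp(beta),
                "ci_low": np.exp(beta - _Z975 * se),
                "ci_high": np.exp(beta + _Z975 * se),
                "p": p,
                "is_rrr": [n.startswith(RRR_PREFIX) for n in beta.index],
            }
        )


def _data_hash(event, time, X) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(event.astype(np.int8)).tobytes())
    h.update(np.ascontiguousarray(time, dtype=np.float64).tobytes())
    h.update(np.ascontiguousarray(X, dtype=np.float64).tobytes())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# Cox partial likelihood


def _cox_groups(time, event):
    """Indices structuring the risk sets: subjects sorted by time ascending,
    and for each distinct event time the slice of tied events plus the
    first index of its risk set."""
    order = np.argsort(time, kind="stable")
    t, d = time[order], event[order]
    groups = []
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        ev = [k for k in range(i, j) if d[k]]
        if ev:
            groups.append((i, np.array(ev)))
        i = j
    return order, groups


def _cox_ll_grad_hess(beta, Xs, *, groups, ties):
    """Efron/Breslow partial log-likelihood with gradient and information.

    ``Xs`` is the design sorted by time ascending; ``groups`` from
    :func:`_cox_groups`.  Returns (ll, grad, info) with info = -Hessian.
    """
    n, p = Xs.shape
    eta = Xs @ beta
    eta_max = eta.max()
    w = np.exp(eta - eta_max)  # common factor cancels in all ratios
    # suffix sums over the risk sets
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w[:, None] * Xs)[::-1], axis=0)[::-1]
    S2 = np.cumsum((w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]))[::-1],
                   axis=0)[::-1]
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    for start, ev in groups:
        m = len(ev)
        s0, s1, s2 = S0[start], S1[start], S2[start]
        ll += eta[ev].sum() - m * eta_max
        grad += Xs[ev].sum(axis=0)
        if ties == "efron" and m > 1:
            frac = np.arange(m) / m
            s0d = w[ev].sum()
            s1d = (w[ev, None] * Xs[ev]).sum(axis=0)
            s2d = np.einsum("i,ij,ik->jk", w[ev], Xs[ev], Xs[ev])
            phi = s0 - frac * s0d                       # (m,)
            M = (s1[None, :] - frac[:, None] * s1d) / phi[:, None]
            ll -= np.log(phi).sum()
            grad -= M.sum(axis=0)
            info += (s2 * (1.0 / phi).sum() - s2d * (frac / phi).sum()) - M.T @ M
        else:  # Breslow, or a single event
            ll -= m * np.log(s0)
            mbar = s1 / s0
            grad -= m * mbar
            info += m * (s2 / s0 - np.outer(mbar, mbar))
    return ll, grad, info


class CoxPH(BaseEstimator):
    """Cox proportional-hazards regression (partial likelihood).

    Parameters
    ----------
    ties : {"efron", "breslow"}
        Tie-handling approximation.  Transformed relative-survival times
        are continuous so ties are rare, but file rounding can create them.
    tol : float
        Convergence tolerance on the max-norm of the score vector.
    max_iter : int
        Newton iteration budget.

    Attributes (after ``fit``)
    --------------------------
    coef_ : ndarray — maximum partial-likelihood estimates
    cov_ : ndarray — inverse observed information
    loglik_ : float — partial log-likelihood at the optimum
    n_iter_ : int
    feature_names_in_ : list of str
    result_ : FitResult
    """

    def __init__(self, ties="efron", tol=1e-9, max_iter=100):
        self.ties = ties
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        if self.ties not in ("efron", "breslow"):
            raise ValidationError(f"unknown tie method {self.ties!r}")
        Xm, names = _as_matrix(X)
        event, time = _unpack_y(y)
        if len(event) != Xm.shape[0]:
            raise ValidationError("X and y lengths differ")
        if event.sum() < 1:
            raise ValidationError("at least one event is required")
        if np.any(time < 0) or not np.all(np.isfinite(time)):
            raise ValidationError("times must be finite and >= 0")
        _check_rank(Xm, names)

        order, groups = _cox_groups(time, event)
        Xs = Xm[order]
        p = Xm.shape[1]
        beta = np.zeros(p)
        ll, grad, info = _cox_ll_grad_hess(beta, Xs, groups=groups, ties=self.ties)
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            if np.max(np.abs(grad)) < self.tol:
                break
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(info, grad, rcond=None)[0]
            # step-halving keeps the partial likelihood non-decreasing
            factor, accepted = 1.0, False
            for _ in range(40):
                cand = beta + factor * step
                ll_new, grad_new, info_new = _cox_ll_grad_hess(
                    cand, Xs, groups=groups, ties=self.ties
                )
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12 * max(1.0, abs(ll)):
                    beta, ll, grad, info = cand, ll_new, grad_new, info_new
                    accepted = True
                    break
                factor *= 0.5
            if not accepted:
                raise ConvergenceError(
                    f"step-halving failed at iteration {n_iter} "
                    f"(score norm {np.max(np.abs(grad)):.3g})"
                )
            if np.max(np.abs(beta)) > 20:
                worst = names[int(np.argmax(np.abs(beta)))]
                raise ConvergenceError(
                    f"monotone partial likelihood: coefficient for {worst!r} "
                    "diverges (perfect separation of events)"
                )
        if np.max(np.abs(grad)) >= self.tol:
            raise ConvergenceError(
                f"Cox fit did not converge in {self.max_iter} iterations "
                f"(score norm {np.max(np.abs(grad)):.3g})"
            )
        self.coef_ = beta
        self.cov_ = np.linalg.inv(info)
        self.loglik_ = ll
        self.n_iter_ = n_iter
        self.feature_names_in_ = names
        params = pd.Series(beta, index=names)
        self.result_ = FitResult(
            family="cox",
            params=params,
            cov=pd.DataFrame(self.cov_, index=names, columns=names),
            loglik=ll,
            n=len(time),
            n_events=int(event.sum()),
            scale_axis="z",
            covariate_names=names,
            data_hash=_data_hash(event, time, Xm),
            model=self,
        )
        return self

    def predict(self, X):
        """Linear predictor (log relative hazard) for new rows."""
        Xm, _ = _as_matrix(X)
        return Xm @ self.coef_


# ---------------------------------------------------------------------------
# Weibull PH likelihood


def _weibull_ll_parts(theta, Xm, event, logz, z, fixed_shape):
    """Log-likelihood, gradient and information for the Weibull PH model.

    theta = (beta..., alpha[, gamma]) with lam = exp(alpha), k = exp(gamma);
    gamma is omitted when the shape is fixed.
    """
    p = Xm.shape[1]
    beta = theta[:p]
    alpha = theta[p]
    gamma = np.log(fixed_shape) if fixed_shape is not None else theta[p + 1]
    k = np.exp(gamma)
    eta = Xm @ beta
    u = k * logz                       # k log z
    logH = alpha + u + eta
    H = np.exp(logH)
    d = event.astype(float)
    nd = d.sum()

    ll = (d * (gamma + alpha + (k - 1.0) * logz + eta)).sum() - H.sum()

    g_beta = Xm.T @ (d - H)
    g_alpha = nd - H.sum()
    grad = [g_beta, [g_alpha]]
    if fixed_shape is None:
        g_gamma = (d * (1.0 + u)).sum() - (H * u).sum()
        grad.append([g_gamma])
    grad = np.concatenate([np.atleast_1d(np.asarray(g)) for g in grad])

    # information = -Hessian
    HX = H[:, None] * Xm
    I_bb = Xm.T @ HX
    I_ba = HX.sum(axis=0)
    dim = p + 1 + (0 if fixed_shape is not None else 1)
    info = np.zeros((dim, dim))
    info[:p, :p] = I_bb
    info[:p, p] = I_ba
    info[p, :p] = I_ba
    info[p, p] = H.sum()
    if fixed_shape is None:
        Hu = H * u
        I_bg = Xm.T @ Hu
        I_ag = Hu.sum()
        I_gg = (H * (u ** 2 + u)).sum() - (d * u).sum()
        info[:p, p + 1] = I_bg
        info[p + 1, :p] = I_bg
        info[p, p + 1] = I_ag
        info[p + 1, p] = I_ag
        info[p + 1, p + 1] = I_gg
    return ll, grad, info


class WeibullPH(BaseEstimator):
    """Weibull proportional-hazards regression with censoring.

    ``h(z|x) = k * lam * z**(k-1) * exp(x @ beta)``; the times must be the
    ``Z`` relative-survival measure (strictly positive for events).  With
    ``fix_shape=1`` the model is exponential.

    Attributes (after ``fit``): ``coef_``, ``shape_`` (k), ``rate_`` (lam),
    ``cov_`` (covariance of (beta, log lam[, log k])), ``loglik_``,
    ``result_``.
    """

    def __init__(self, fix_shape=None, tol=1e-6, max_iter=200):
        self.fix_shape = fix_shape
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        Xm, names = _as_matrix(X)
        event, time = _unpack_y(y)
        if len(event) != Xm.shape[0]:
            raise ValidationError("X and y lengths differ")
        if event.sum() < 1:
            raise ValidationError("at least one event is required")
        if np.any(time[event] <= 0):
            raise ValidationError("event times must be strictly positive on the Z scale")
        if np.any(time < 0) or not np.all(np.isfinite(time)):
            raise ValidationError("times must be finite and >= 0")
        if Xm.shape[1]:
            _check_rank(Xm, names)
        if self.fix_shape is not None and self.fix_shape <= 0:
            raise ValidationError("fix_shape must be positive")

        z = np.maximum(time, 1e-300)
        logz = np.log(z)
        p = Xm.shape[1]
        dim = p + 1 + (0 if self.fix_shape is not None else 1)
        theta = np.zeros(dim)
        k0 = self.fix_shape if self.fix_shape is not None else 1.0
        theta[p] = np.log(event.sum() / np.sum(z ** k0))  # exponential-rate start

        ll, grad, info = _weibull_ll_parts(theta, Xm, event, logz, z, self.fix_shape)
        ok = False
        for _ in range(self.max_iter):
            if np.max(np.abs(grad)) < self.tol:
                ok = True
                break
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError:
                step = grad / max(1.0, np.abs(np.diag(info)).max())
            factor, accepted = 1.0, False
            for _ in range(40):
                cand = theta + factor * step
                ll_new, grad_new, info_new = _weibull_ll_parts(
                    cand, Xm, event, logz, z, self.fix_shape
                )
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12 * max(1.0, abs(ll)):
                    theta, ll, grad, info = cand, ll_new, grad_new, info_new
                    accepted = True
                    break
                factor *= 0.5
            if not accepted:
                break
        if not ok and np.max(np.abs(grad)) >= self.tol:
            # quasi-Newton fallback for awkward curvature
            res = optimize.minimize(
                lambda th: -_weibull_ll_parts(th, Xm, event, logz, z, self.fix_shape)[0],
                theta,
                jac=lambda th: -_weibull_ll_parts(th, Xm, event, logz, z, self.fix_shape)[1],
                method="BFGS",
                options={"gtol": self.tol / 10, "maxiter": 500},
            )
            theta = res.x
            ll, grad, info = _weibull_ll_parts(theta, Xm, event, logz, z, self.fix_shape)
            if np.max(np.abs(grad)) >= self.tol * 100:
                raise ConvergenceError(
                    "Weibull fit did not converge; last gradient max-norm "
                    f"{np.max(np.abs(grad)):.3g}"
                )

        beta = theta[:p]
        alpha = theta[p]
        gamma = np.log(self.fix_shape) if self.fix_shape is not None else theta[p + 1]
        self.coef_ = beta
        self.rate_ = float(np.exp(alpha))
        self.shape_ = float(np.exp(gamma))
        self.loglik_ = float(ll)
        self.cov_ = np.linalg.inv(info)
        self.feature_names_in_ = names
        pnames = names + ["log_rate"] + ([] if self.fix_shape is not None else ["log_shape"])
        self.result_ = FitResult(
            family="exponential" if self.fix_shape == 1 else "weibull",
            params=pd.Series(theta, index=pnames),
            cov=pd.DataFrame(self.cov_, index=pnames, columns=pnames),
            loglik=float(ll),
            n=len(time),
            n_events=int(event.sum()),
            scale_axis="z",
            covariate_names=names,
            shape=self.shape_,
            rate=self.rate_,
            data_hash=_data_hash(event, time, Xm),
            model=self,
        )
        return self

    def predict(self, X):
        """Linear predictor (log relative hazard) for new rows."""
        Xm, _ = _as_matrix(X)
        return Xm @ self.coef_


# ---------------------------------------------------------------------------
# Functional wrappers over the estimators


def _records_to_y(records: pd.DataFrame, scale: str):
    if not {"event", scale} <= set(records.columns):
        raise ValidationError(f"records need 'event' and {scale!r} columns")
    return survival_array(records["event"].to_numpy(), records[scale].to_numpy(float))


def fit_cox(records: pd.DataFrame, X, spec: ModelSpec = ModelSpec()) -> FitResult:
    """Fit the Cox model to transformed records on the spec's time scale."""
    y = _records_to_y(records, spec.scale)
    est = CoxPH(ties=spec.ties, tol=spec.tol, max_iter=spec.max_iter).fit(X, y)
    est.result_.scale_axis = spec.scale
    return est.result_

def fit_weibull(records: pd.DataFrame, X, spec: ModelSpec = ModelSpec(family="weibull"),
                fix_shape=None) -> FitResult:
    """Fit the Weibull PH model to the Z-scale transformed records.

    The ``Y`` scale is refused: a bounded measure cannot carry a Weibull
    hazard, and the parametric predictions all live on ``Z``.
    """
    if spec.scale != "z":
        raise ValidationError("the parametric family requires the Z time scale")
    if spec.family == "exponential" and fix_shape is None:
        fix_shape = 1.0
    y = _records_to_y(records, "z")
    est = WeibullPH(fix_shape=fix_shape, max_iter=spec.max_iter).fit(X, y)
    return est.result_


def extract_rrr(fit: FitResult, scheme: Optional[str] = None) -> pd.DataFrame:
    """Female-to-male relative risk ratios from a fitted model.

    One row per gender-by-grade interaction: the RRR (exp of the
    interaction coefficient), its Wald 95% CI and p-value.  Algebraically
    the RRR equals (female smoker vs female never) / (male smoker vs male
    never) on the fitted hazard-ratio scale.
    """
    rows = [n for n in fit.covariate_names if n.startswith(RRR_PREFIX)]
    if scheme is not None:
        expected = {
            "rrr4": ["fem_x_light", "fem_x_medium", "fem_x_heavy", "fem_x_former"],
            "rrr3": ["fem_x_light", "fem_x_medheavy", "fem_x_former"],
        }.get(scheme)
        if expected is None:
            raise ValidationError(f"unknown scheme {scheme!r}")
        missing = [c for c in expected if c not in rows]
        if missing:
            raise ValidationError(f"fit lacks interaction columns: {missing}")
        rows = expected
    if not rows:
        raise ValidationError("fit contains no gender-by-grade interaction columns")
    s = fit.summary().loc[rows]
    out = s[["hr", "ci_low", "ci_high", "p"]].rename(columns={"hr": "rrr"})
    out.index = [r[len(RRR_PREFIX):] for r in rows]
    out.index.name = "grade"
    return out


def compare_models(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Rank fitted models of the same data by log-likelihood.

    Ties are broken in favour of fewer parameters, then input order.
    Fits of different data (mismatched hashes) are refused.
    """
    fits = list(fits)
    if not fits:
        raise ValidationError("no fits to compare")
    h0 = fits[0].data_hash
    if any(f.data_hash != h0 for f in fits):
        raise ValidationError("fits were made on different data (hash mismatch)")
    order = sorted(
        range(len(fits)),
        key=lambda i: (-fits[i].loglik, fits[i].n_params, i),
    )
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(fits) + 1),
            "family": [fits[i].family for i in order],
            "loglik": [fits[i].loglik for i in order],
            "n_params": [fits[i].n_params for i in order],
            "input_index": order,
        }
    ).set_index("rank")
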