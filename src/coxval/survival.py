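"""Censored-data primitives: Kaplan-Meier, Cox partial likelihood, Breslow baseline.

Kaplan-Meier estimation is delegated to lifelines and re-exposed as a plain
step-function container.  The Cox fitter is implemented here directly: a
Newton iteration on the partial likelihood with Breslow tie handling by
default (Efron optional), step-halving on overshoot, and standard errors from
the observed information.  Having the fitter in-package is what lets the
recalibration layer (a) refit a published term structure on a new cohort and
(b) re-estimate only the baseline survival with the published coefficients
held fixed, by treating the published linear predictor as an offset in the
Breslow baseline-hazard estimator.

Time is measured in years throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from ._exceptions import ConvergenceWarning, FitError

__all__ = [
    "SurvivalCurve",
    "CoxFitResult",
    "kaplan_meier",
    "fit_cox",
    "breslow_baseline_survival",
]


@dataclass(frozen=True)
class SurvivalCurve:
    """A right-continuous non-increasing survival step function.

    ``times`` holds the (ascending) event times where the curve steps;
    ``survival`` the value S(t) just after each step; ``at_risk`` and
    ``events`` the risk-set size and event count at each step.  Before the
    first event S(t) = 1; after ``support_end`` (the largest observed
    follow-up time) the curve is no longer informed by data.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    support_end: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        surv = np.asarray(self.survival, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "survival", surv)
        object.__setattr__(self, "at_risk", np.asarray(self.at_risk, dtype=int))
        object.__setattr__(self, "events", np.asarray(self.events, dtype=int))
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise ValueError("curve times must be strictly increasing")
            if np.any(np.diff(surv) > 1e-12):
                raise ValueError("survival values must be non-increasing")
            if surv[0] > 1.0 + 1e-12 or np.any(surv < 0):
                raise ValueError("survival values must lie in [0, 1]")

    def survival_at(self, t: float | np.ndarray) -> float | np.ndarray:
        """S(t) of the step function (1 before the first event)."""
        t_arr = np.asarray(t, dtype=float)
        if self.times.size == 0:
            out = np.ones_like(t_arr, dtype=float)
        else:
            idx = np.searchsorted(self.times, t_arr, side="right") - 1
            out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return float(out) if np.ndim(t) == 0 else out

    def cumulative_hazard_at(self, t: float | np.ndarray) -> float | np.ndarray:
        s = self.survival_at(t)
        return -np.log(s)


@dataclass(frozen=True)
class CoxFitResult:
    """Result of a Cox partial-likelihood fit."""

    coefficients: Mapping[str, float]
    standard_errors: Mapping[str, float]
    covariance: pd.DataFrame
    baseline_survival_curve: SurvivalCurve
    log_partial_likelihood: float
    converged: bool
    n_iterations: int
    n_subjects: int
    n_events: int
    ties: str = "breslow"
    covariate_means: Mapping[str, float] = field(default_factory=dict)


def _validate_times_events(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    if e.dtype != bool:
        e = np.asarray(e, dtype=float) != 0
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-d array")
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if np.any(~np.isfinite(t)) or np.any(t < 0):
        raise ValueError("follow-up times must be finite and non-negative")
    return t, e


def kaplan_meier(times, events) -> SurvivalCurve:
    """Product-limit survival estimate, S(t) = prod_{t_i <= t} (1 - d_i/n_i)."""
    t, e = _validate_times_events(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    if len(ev) == 0:
        return SurvivalCurve(
            times=np.array([]), survival=np.array([]), at_risk=np.array([]),
            events=np.array([]), support_end=float(t.max()),
        )
    surv = kmf.survival_function_["KM_estimate"].reindex(ev.index).to_numpy()
    return SurvivalCurve(
        times=ev.index.to_numpy(dtype=float),
        survival=surv,
        at_risk=ev["at_risk"].to_numpy(),
        events=ev["observed"].to_numpy(),
        support_end=float(t.max()),
    )


# -- Cox partial likelihood ---------------------------------------------------


def _partial_likelihood_parts(beta, X, times, events, ties):
    """Log partial likelihood, score vector and observed information.

    Arrays must be pre-sorted by ascending time.  Breslow and Efron tie
    corrections share one vectorised path: each event contributes a row with
    an Efron fraction l/d (0 for Breslow).
    """
    n, p = X.shape
    eta = X @ beta
    # guard against overflow during step search; the halving loop rejects inf
    with np.errstate(over="ignore"):
        w = np.exp(eta)
    if not np.all(np.isfinite(w)):
        return -np.inf, None, None
    xw = X * w[:, None]
    # reverse cumulative risk-set sums
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(xw[::-1], axis=0)[::-1]
    outer = X[:, :, None] * xw[:, None, :]
    s2 = np.cumsum(outer[::-1], axis=0)[::-1]

    ev_idx = np.flatnonzero(events)
    ut, first_pos = np.unique(times[ev_idx], return_index=True)
    # index of the first subject (any status) with time >= each unique event time
    risk_idx = np.searchsorted(times, ut, side="left")
    d = np.diff(np.append(first_pos, ev_idx.size))  # events per unique time

    # tied-event sums per unique event time
    bounds = first_pos
    w_ev = w[ev_idx]
    wtie = np.add.reduceat(w_ev, bounds)
    s1tie = np.add.reduceat(xw[ev_idx], bounds, axis=0)
    s2tie = np.add.reduceat(outer[ev_idx], bounds, axis=0)

    rep = np.repeat(np.arange(ut.size), d)
    if ties == "efron":
        l = np.concatenate([np.arange(k) for k in d]) if d.size else np.array([])
        frac = l / d[rep]
    else:
        frac = np.zeros(ev_idx.size)

    denom = s0[risk_idx][rep] - frac * wtie[rep]
    if np.any(denom <= 0):
        return -np.inf, None, None
    num1 = s1[risk_idx][rep] - frac[:, None] * s1tie[rep]
    num2 = s2[risk_idx][rep] - frac[:, None, None] * s2tie[rep]

    loglik = float(eta[ev_idx].sum() - np.log(denom).sum())
    mu = num1 / denom[:, None]
    score = X[ev_idx].sum(axis=0) - mu.sum(axis=0)
    info = (num2 / denom[:, None, None]).sum(axis=0) - mu.T @ mu
    return loglik, score, info


def fit_cox(
    X: pd.DataFrame,
    times,
    events,
    ties: str = "breslow",
    max_iter: int = 100,
    tol: float = 1e-9,
) -> CoxFitResult:
    """Maximise the Cox partial likelihood by Newton iteration.

    Parameters
    ----------
    X : DataFrame
        Design matrix, one column per covariate (already on the transform
        scale the risk equation uses).
    times, events : array-like
        Follow-up years and event indicators.
    ties : {"breslow", "efron"}
        Tie-handling approximation for the partial likelihood.

    Convergence is declared when the relative change in log partial
    likelihood falls below ``tol``; on overshoot the Newton step is halved.
    Non-convergence is flagged on the result (and warned), never silent.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError(f"ties must be 'breslow' or 'efron', got {ties!r}")
    if not isinstance(X, pd.DataFrame):
        raise TypeError("X must be a DataFrame with named covariate columns")
    t, e = _validate_times_events(times, events)
    n, p = X.shape
    if n < 2:
        raise FitError("at least 2 subjects are required to fit a Cox model")
    if len(t) != n:
        raise ValueError("X and times must have equal length")
    if e.sum() == 0:
        raise FitError("no events in the cohort; the partial likelihood is flat")
    if p == 0:
        raise FitError("no covariates supplied")
    Xv = X.to_numpy(dtype=float)
    if not np.all(np.isfinite(Xv)):
        raise FitError("design matrix contains non-finite values")
    for j, name in enumerate(X.columns):
        if np.ptp(Xv[:, j]) == 0:
            raise FitError(f"covariate {name!r} is constant; it cannot be estimated")

    order = np.argsort(t, kind="stable")
    ts, es, Xs = t[order], e[order], Xv[order]
    # centre columns for numerical stability (shifts cancel in the partial likelihood)
    col_means = Xs.mean(axis=0)
    Xc = Xs - col_means

    beta = np.zeros(p)
    loglik, score, info = _partial_likelihood_parts(beta, Xc, ts, es, ties)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise FitError(
                "singular information matrix (collinear covariates?)"
            ) from exc
        new_beta, new_ll = beta, loglik
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            cand_ll, cand_score, cand_info = _partial_likelihood_parts(
                cand, Xc, ts, es, ties
            )
            if np.isfinite(cand_ll) and cand_ll >= loglik - 1e-12:
                new_beta, new_ll = cand, cand_ll
                score, info = cand_score, cand_info
                break
            scale *= 0.5
        else:
            break  # no ascent direction found
        if abs(new_ll - loglik) <= tol * max(1.0, abs(loglik)):
            beta, loglik = new_beta, new_ll
            converged = True
            break
        beta, loglik = new_beta, new_ll
    if not converged:
        warnings.warn(
            f"Cox fit did not converge in {it} iterations", ConvergenceWarning,
            stacklevel=2,
        )

    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise FitError("information matrix not invertible at the optimum") from exc
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    names = list(X.columns)
    lp = Xv @ beta  # uncentred linear predictor
    means = {name: float(m) for name, m in zip(names, Xv.mean(axis=0))}
    center = float(np.dot(list(means.values()), beta))
    baseline = breslow_baseline_survival(t, e, lp, center=center)
    return CoxFitResult(
        coefficients={name: float(b) for name, b in zip(names, beta)},
        standard_errors={name: float(s) for name, s in zip(names, se)},
        covariance=pd.DataFrame(cov, index=names, columns=names),
        baseline_survival_curve=baseline,
        log_partial_likelihood=float(loglik),
        converged=converged,
        n_iterations=it,
        n_subjects=int(n),
        n_events=int(e.sum()),
        ties=ties,
        covariate_means=means,
    )


def breslow_baseline_survival(times, events, linear_predictor, center: float = 0.0) -> SurvivalCurve:
    """Breslow baseline survival at a stated centering point.

    With coefficients (hence per-subject linear predictors) held fixed, the
    cumulative baseline hazard for a subject whose linear predictor equals
    ``center`` is

        H0(t) = sum_{event times t_k <= t} d_k / sum_{j at risk} exp(lp_j - center)

    and S0(t) = exp(-H0(t)).  This is the estimator the adjusted model tier
    uses to replace a published baseline survival with a cohort-derived one
    while leaving the published coefficients untouched.
    """
    t, e = _validate_times_events(times, events)
    lp = np.asarray(linear_predictor, dtype=float)
    if lp.shape != t.shape:
        raise ValueError("linear_predictor must have one value per subject")
    order = np.argsort(t, kind="stable")
    ts, es, lps = t[order], e[order], lp[order] - center
    w = np.exp(lps)
    s0 = np.cumsum(w[::-1])[::-1]
    ev_idx = np.flatnonzero(es)
    if ev_idx.size == 0:
        return SurvivalCurve(
            times=np.array([]), survival=np.array([]), at_risk=np.array([]),
            events=np.array([]), support_end=float(t.max()),
        )
    ut, first_pos = np.unique(ts[ev_idx], return_index=True)
    risk_idx = np.searchsorted(ts, ut, side="left")
    d = np.diff(np.append(first_pos, ev_idx.size))
    increments = d / s0[risk_idx]
    h0 = np.cumsum(increments)
    at_risk = (ts.size - risk_idx).astype(int)
    return SurvivalCurve(
        times=ut,
        survival=np.exp(-h0),
        at_risk=at_risk,
        events=d.astype(int),
        support_end=float(t.max()),
    )
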