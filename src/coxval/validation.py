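"""Validation battery for absolute-risk scores on a censored cohort.

Four complementary views of model performance:

* **Calibration** — subjects are grouped into deciles of predicted risk; in
  each group the Kaplan-Meier "observed" risk ``k_g = 1 - S_g(horizon)`` is
  compared with the mean predicted risk ``pbar_g`` through a
  Hosmer-Lemeshow-type statistic

      chi2 = sum_g n_g (k_g - pbar_g)^2 / (pbar_g (1 - pbar_g)),

  referred to a chi-square distribution on G - 2 degrees of freedom.  With the
  conventional 10 groups this puts the 1% critical value at 20.09, i.e. a
  chi-square above 20 flags significant lack of calibration.
* **Discrimination** — the C statistic (probability that a random event
  subject is scored above a random non-event subject, ties half-weighted),
  with variance from the DeLong structural components; differences between two
  paired scores are tested with the DeLong method.
* **Reclassification** — the category-less (continuous) net reclassification
  improvement: the net fraction of events whose risk moves up plus the net
  fraction of non-events whose risk moves down when switching scores.
* **IDI** — the change in discrimination slope (mean predicted risk in events
  minus in non-events).

Event status at the horizon is binary: an event subject had the event by the
horizon; a non-event subject was followed at least to the horizon.  Subjects
censored before the horizon without an event carry no binary outcome and are
excluded from C/NRI/IDI (their count is reported); the Kaplan-Meier estimator
handles censoring on the calibration side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import CalibrationWarning, DataWarning
from .survival import kaplan_meier

__all__ = [
    "status_at_horizon",
    "calibration_chi2",
    "expected_vs_observed",
    "c_statistic",
    "delong_compare",
    "continuous_nri",
    "idi",
    "reclassification",
    "CalibrationTable",
    "DiscriminationResult",
    "DeLongResult",
    "ReclassificationResult",
]

_Z975 = float(stats.norm.ppf(0.975))


def status_at_horizon(times, events, horizon: float):
    """Binary event status by the horizon and the usable-subject mask.

    Returns ``(status, include)``: ``status[i]`` is True when subject i had
    the event at or before the horizon; ``include[i]`` is False for subjects
    censored before the horizon without an event (no binary outcome exists
    for them).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(bool)
    status = e & (t <= horizon)
    include = status | (t >= horizon)
    return status, include


# -- calibration --------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationTable:
    """Per-decile predicted vs Kaplan-Meier observed risk with the HL chi2."""

    table: pd.DataFrame
    chi2: float
    df: int
    p_value: float
    horizon: float
    n_groups_requested: int
    flagged_groups: tuple[int, ...] = ()

    @property
    def n(self) -> int:
        return int(self.table["n"].sum())

    def plot_data(self) -> pd.DataFrame:
        """Per-group (predicted, observed) pairs for external plotting."""
        return self.table[["mean_predicted", "km_observed"]].copy()


def calibration_chi2(
    risks, times, events, horizon: float, n_groups: int = 10
) -> CalibrationTable:
    """Decile-based Hosmer-Lemeshow calibration with KM-adjusted observed risk."""
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    r = np.asarray(risks, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(bool)
    if not (len(r) == len(t) == len(e)):
        raise ValueError("risks, times and events must have equal length")
    labels = pd.qcut(pd.Series(r), n_groups, labels=False, duplicates="drop")
    if labels.isna().all():  # constant predicted risk: one merged group
        labels = pd.Series(np.zeros(len(r)))
    g_used = int(labels.max()) + 1
    if g_used < n_groups:
        warnings.warn(
            f"fewer distinct predicted risks than groups: merged to {g_used} groups",
            CalibrationWarning, stacklevel=2,
        )
    if t.max() < horizon:
        warnings.warn(
            f"horizon {horizon} exceeds the last follow-up time {t.max():.3g}; "
            "observed risk evaluated at the last time",
            DataWarning, stacklevel=2,
        )
    rows = []
    flagged = []
    chi2 = 0.0
    for g in range(g_used):
        mask = labels.to_numpy() == g
        n_g = int(mask.sum())
        pbar = float(r[mask].mean())
        km = kaplan_meier(t[mask], e[mask])
        k_g = 1.0 - float(km.survival_at(horizon))
        var = pbar * (1.0 - pbar)
        if var <= 0.0:
            var = 1.0 / (4.0 * n_g)  # continuity floor for degenerate groups
            flagged.append(g)
        term = n_g * (k_g - pbar) ** 2 / var
        chi2 += term
        rows.append(
            {
                "group": g + 1,
                "n": n_g,
                "mean_predicted": pbar,
                "km_observed": k_g,
                "predicted_events": float(r[mask].sum()),
                "observed_events_km": n_g * k_g,
                "chi2_term": term,
            }
        )
    if flagged:
        warnings.warn(
            f"groups {flagged} had degenerate mean predicted risk; variance floored",
            CalibrationWarning, stacklevel=2,
        )
    df = g_used - 2
    p = float(stats.chi2.sf(chi2, df)) if df >= 1 else float("nan")
    return CalibrationTable(
        table=pd.DataFrame(rows),
        chi2=float(chi2),
        df=df,
        p_value=p,
        horizon=float(horizon),
        n_groups_requested=n_groups,
        flagged_groups=tuple(flagged),
    )


class ExpectedObserved(NamedTuple):
    predicted_events: float
    observed_events_km: float


def expected_vs_observed(risks, times, events, horizon: float) -> ExpectedObserved:
    """Total predicted events vs the KM-adjusted observed count n(1 - S(horizon))."""
    r = np.asarray(risks, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(bool)
    if t.max() < horizon:
        warnings.warn(
            "horizon beyond last follow-up time; observed risk evaluated at the last time",
            DataWarning, stacklevel=2,
        )
    km = kaplan_meier(t, e)
    observed = len(r) * (1.0 - float(km.survival_at(horizon)))
    return ExpectedObserved(float(r.sum()), observed)


# -- discrimination -----------------------------------------------------------


@dataclass(frozen=True)
class DiscriminationResult:
    c_statistic: float
    standard_error: float
    ci_lower: float
    ci_upper: float
    n_events: int
    n_nonevents: int
    n_excluded: int = 0


def _delong_components(risks: np.ndarray, status: np.ndarray):
    """C statistic and DeLong structural components via midranks."""
    x = risks[status]
    y = risks[~status]
    m, n = x.size, y.size
    if m == 0 or n == 0:
        raise ValueError("need at least one event and one non-event")
    tz = stats.rankdata(np.concatenate([x, y]))
    tx = stats.rankdata(x)
    ty = stats.rankdata(y)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    auc = float((tz[:m].sum() - m * (m + 1) / 2.0) / (m * n))
    return auc, v10, v01


def c_statistic(risks, status, n_excluded: int = 0) -> DiscriminationResult:
    """C statistic with DeLong structural-components variance.

    ``status`` is the binary event-by-horizon indicator; use
    :func:`status_at_horizon` to derive it (and the excluded count) from
    censored follow-up data.
    """
    r = np.asarray(risks, dtype=float)
    s = np.asarray(status).astype(bool)
    auc, v10, v01 = _delong_components(r, s)
    m, n = v10.size, v01.size
    if m > 1 and n > 1:
        var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
        se = float(np.sqrt(var))
    else:
        se = float("nan")
    lo = float(np.clip(auc - _Z975 * se, 0.0, 1.0)) if np.isfinite(se) else float("nan")
    hi = float(np.clip(auc + _Z975 * se, 0.0, 1.0)) if np.isfinite(se) else float("nan")
    return DiscriminationResult(auc, se, lo, hi, int(m), int(n), int(n_excluded))


@dataclass(frozen=True)
class DeLongResult:
    delta_c: float
    standard_error: float
    ci_lower: float
    ci_upper: float
    p_value: float
    c_a: float
    c_b: float


def delong_compare(risks_a, risks_b, status) -> DeLongResult:
    """DeLong test for the difference of two paired C statistics."""
    a = np.asarray(risks_a, dtype=float)
    b = np.asarray(risks_b, dtype=float)
    s = np.asarray(status).astype(bool)
    if a.shape != b.shape or a.shape != s.shape:
        raise ValueError("risks_a, risks_b and status must be paired (equal length)")
    auc_a, v10_a, v01_a = _delong_components(a, s)
    auc_b, v10_b, v01_b = _delong_components(b, s)
    m, n = v10_a.size, v01_a.size
    delta = auc_a - auc_b
    d10 = v10_a - v10_b
    d01 = v01_a - v01_b
    var = 0.0
    if m > 1:
        var += d10.var(ddof=1) / m
    if n > 1:
        var += d01.var(ddof=1) / n
    se = float(np.sqrt(var))
    if se == 0.0:
        p = 1.0 if delta == 0.0 else 0.0
    else:
        p = float(2.0 * stats.norm.sf(abs(delta) / se))
    return DeLongResult(
        delta_c=float(delta),
        standard_error=se,
        ci_lower=float(delta - _Z975 * se),
        ci_upper=float(delta + _Z975 * se),
        p_value=p,
        c_a=auc_a,
        c_b=auc_b,
    )


# -- reclassification ---------------------------------------------------------


@dataclass(frozen=True)
class ReclassificationResult:
    """Movement counts and category-less NRI (and optionally IDI) with CIs."""

    n_events: int
    n_nonevents: int
    events_up: int
    events_down: int
    nonevents_up: int
    nonevents_down: int
    event_nri: float
    nonevent_nri: float
    total_nri: float
    nri_se: float
    nri_ci: tuple[float, float]
    idi: float | None = None
    idi_se: float | None = None
    idi_ci: tuple[float, float] | None = None
    n_excluded: int = 0
    ci_method: str = "analytic"


def _paired_status(risks_old, risks_new, status):
    old = np.asarray(risks_old, dtype=float)
    new = np.asarray(risks_new, dtype=float)
    s = np.asarray(status).astype(bool)
    if old.shape != new.shape or old.shape != s.shape:
        raise ValueError("risks_old, risks_new and status must be paired (equal length)")
    if s.all() or (~s).all():
        raise ValueError("need at least one event and one non-event")
    return old, new, s


def continuous_nri(
    risks_old,
    risks_new,
    status,
    n_excluded: int = 0,
    ci_method: str = "analytic",
    n_boot: int = 2000,
    rng=None,
) -> ReclassificationResult:
    """Category-less net reclassification improvement, new score vs old.

    "Up" means the new risk is strictly greater than the old; ties move
    neither way but stay in the denominators.  Event NRI =
    (up_e - down_e)/n_e, non-event NRI = (down_ne - up_ne)/n_ne, total is
    their sum (range -2..2).  The CI is asymptotic normal by default; pass
    ``ci_method="bootstrap"`` (with an optional seeded ``rng``) to resample
    subjects instead.
    """
    old, new, s = _paired_status(risks_old, risks_new, status)
    up = new > old
    down = new < old
    n_e = int(s.sum())
    n_ne = int((~s).sum())
    up_e, down_e = int((up & s).sum()), int((down & s).sum())
    up_ne, down_ne = int((up & ~s).sum()), int((down & ~s).sum())
    event_nri = (up_e - down_e) / n_e
    nonevent_nri = (down_ne - up_ne) / n_ne
    total = event_nri + nonevent_nri

    if ci_method == "analytic":
        pu_e, pd_e = up_e / n_e, down_e / n_e
        pu_ne, pd_ne = up_ne / n_ne, down_ne / n_ne
        var_e = (pu_e + pd_e - (pu_e - pd_e) ** 2) / n_e
        var_ne = (pu_ne + pd_ne - (pd_ne - pu_ne) ** 2) / n_ne
        se = float(np.sqrt(var_e + var_ne))
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(rng)
        idx_e = np.flatnonzero(s)
        idx_ne = np.flatnonzero(~s)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            be = rng.choice(idx_e, n_e, replace=True)
            bn = rng.choice(idx_ne, n_ne, replace=True)
            e_nri = (int((up[be]).sum()) - int((down[be]).sum())) / n_e
            ne_nri = (int((down[bn]).sum()) - int((up[bn]).sum())) / n_ne
            reps[b] = e_nri + ne_nri
        se = float(reps.std(ddof=1))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    ci = (float(total - _Z975 * se), float(total + _Z975 * se))
    return ReclassificationResult(
        n_events=n_e,
        n_nonevents=n_ne,
        events_up=up_e,
        events_down=down_e,
        nonevents_up=up_ne,
        nonevents_down=down_ne,
        event_nri=float(event_nri),
        nonevent_nri=float(nonevent_nri),
        total_nri=float(total),
        nri_se=se,
        nri_ci=ci,
        n_excluded=int(n_excluded),
        ci_method=ci_method,
    )


class IDIResult(NamedTuple):
    idi: float
    standard_error: float
    ci_lower: float
    ci_upper: float


def idi(risks_old, risks_new, status) -> IDIResult:
    """Integrated discrimination improvement: change in discrimination slope.

    IDI = (mean new risk - mean old risk among events)
        - (mean new risk - mean old risk among non-events),
    with the standard error from the paired per-subject differences.
    """
    old, new, s = _paired_status(risks_old, risks_new, status)
    d = new - old
    d_e, d_ne = d[s], d[~s]
    value = float(d_e.mean() - d_ne.mean())
    var = 0.0
    if d_e.size > 1:
        var += d_e.var(ddof=1) / d_e.size
    if d_ne.size > 1:
        var += d_ne.var(ddof=1) / d_ne.size
    se = float(np.sqrt(var))
    return IDIResult(value, se, float(value - _Z975 * se), float(value + _Z975 * se))


def reclassification(
    risks_old, risks_new, status, n_excluded: int = 0, **nri_kwargs
) -> ReclassificationResult:
    """Continuous NRI and IDI in one result (new score vs old)."""
    res = continuous_nri(risks_old, risks_new, status, n_excluded=n_excluded, **nri_kwargs)
    i = idi(risks_old, risks_new, status)
    return ReclassificationResult(
        **{
            **{f.name: getattr(res, f.name) for f in res.__dataclass_fields__.values()},
            "idi": i.idi,
            "idi_se": i.standard_error,
            "idi_ci": (i.ci_lower, i.ci_upper),
        }
    )
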