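"""Three-tier model updating for external validation.

A published risk equation applied to a new cohort can be used in three
versions of increasing local adaptation:

* **original** — exactly as published: source coefficients, source covariate
  means, source baseline survival.
* **adjusted** — the covariate means and the baseline survival are replaced
  by values derived from the validation cohort; the published coefficients
  are kept bitwise unchanged.  The cohort baseline survival is the Breslow
  baseline of a Cox model whose linear predictor is fixed at the published
  coefficients (entered as an offset), so "coefficients unchanged" holds
  literally.
* **recalibrated** — the coefficients themselves are refit on the validation
  cohort with the identical term structure; means and baseline survival are
  cohort-derived as in the adjusted tier.

All functions return new :class:`~coxval.models.CoefficientSet` objects; the
input set is never mutated (it is a frozen dataclass).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from ._exceptions import DataWarning, RangeError
from .models import CoefficientSet, design_matrix
from .survival import breslow_baseline_survival, fit_cox

__all__ = ["adjust_model", "recalibrate_model", "check_tier_invariants"]


def _cohort_arrays(cohort: pd.DataFrame, cset: CoefficientSet):
    if "sex" in cohort.columns:
        sexes = set(cohort["sex"].astype(str))
        if sexes - {cset.sex}:
            raise ValueError(
                f"cohort contains sexes {sorted(sexes)}; restrict it to {cset.sex!r} first"
            )
    times = cohort["follow_up_time"].to_numpy(dtype=float)
    events = cohort["event"].to_numpy()
    design = design_matrix(cohort, cset.terms)
    return times, events, design


def _check_horizon(horizon: float, times: np.ndarray) -> None:
    if horizon > times.max():
        raise RangeError(
            f"horizon {horizon} exceeds the cohort's maximum follow-up "
            f"({times.max():.3g} years)"
        )


def adjust_model(cset: CoefficientSet, cohort: pd.DataFrame, horizon: float) -> CoefficientSet:
    """Adjusted tier: cohort means and cohort baseline survival, coefficients kept.

    The published linear predictor (from the unchanged coefficients) is held
    fixed while the Breslow baseline hazard is re-estimated on the cohort and
    evaluated at the new covariate means.
    """
    times, events, design = _cohort_arrays(cohort, cset)
    _check_horizon(horizon, times)
    beta = np.array([t.coefficient for t in cset.terms])
    lp = design.to_numpy() @ beta
    new_means = {name: float(m) for name, m in design.mean().items()}
    center = float(np.dot(list(new_means.values()), beta))
    curve = breslow_baseline_survival(times, events, lp, center=center)
    s0 = float(curve.survival_at(horizon))
    out = dataclasses.replace(
        cset,
        tier="adjusted",
        horizon=float(horizon),
        baseline_survival=s0,
        covariate_means=new_means,
    )
    check_tier_invariants(cset, out)
    return out


def recalibrate_model(
    cset: CoefficientSet, cohort: pd.DataFrame, horizon: float, ties: str = "breslow"
) -> CoefficientSet:
    """Recalibrated tier: coefficients refit on the cohort, means and S0 cohort-derived.

    The refit uses the identical term structure (transforms and activation
    conditions preserved; only coefficient values change).  Fewer than 10
    events per term triggers a warning — external validation cohorts are often
    small, so this is advisory, not fatal.
    """
    times, events, design = _cohort_arrays(cohort, cset)
    _check_horizon(horizon, times)
    n_events = int(np.asarray(events).astype(bool).sum())
    if n_events < 10 * len(cset.terms):
        warnings.warn(
            f"{n_events} events for {len(cset.terms)} terms "
            f"(<10 events per term); refit coefficients may be unstable",
            DataWarning, stacklevel=2,
        )
    # A predictor the cohort never measured (assume-zero, hence an all-zero
    # column) is inert for scoring and cannot be refit: keep its published
    # coefficient and exclude it from the refit design.
    inert = [
        t.name
        for t in cset.terms
        if t.assume_zero_if_missing and np.ptp(design[t.name].to_numpy()) == 0
    ]
    if inert:
        warnings.warn(
            f"terms {inert} are constant in this cohort (unmeasured predictors); "
            "their published coefficients are kept",
            DataWarning, stacklevel=2,
        )
    fit_design = design.drop(columns=inert)
    fit = fit_cox(fit_design, times, events, ties=ties)
    new_terms = tuple(
        dataclasses.replace(t, coefficient=fit.coefficients.get(t.name, t.coefficient))
        for t in cset.terms
    )
    new_means = {name: float(m) for name, m in design.mean().items()}
    beta = np.array([t.coefficient for t in new_terms])
    lp = design.to_numpy() @ beta
    center = float(np.dot(list(new_means.values()), beta))
    curve = breslow_baseline_survival(times, events, lp, center=center)
    s0 = float(curve.survival_at(horizon))
    out = dataclasses.replace(
        cset,
        tier="recalibrated",
        horizon=float(horizon),
        baseline_survival=s0,
        covariate_means=new_means,
        terms=new_terms,
    )
    check_tier_invariants(cset, out)
    return out


def check_tier_invariants(original: CoefficientSet, updated: CoefficientSet) -> None:
    """Assert the structural contract between an input set and its updated tier.

    * adjusted: identical coefficients and term structure; only means,
      baseline survival (and horizon) may differ;
    * recalibrated: identical term structure (names, transforms, conditions,
      assume-zero flags); coefficient values free.
    """
    if updated.tier == "adjusted":
        if updated.terms != original.terms:
            raise AssertionError("adjusted tier must keep coefficients and terms unchanged")
    elif updated.tier == "recalibrated":
        for t_old, t_new in zip(original.terms, updated.terms):
            stripped_old = dataclasses.replace(t_old, coefficient=0.0)
            stripped_new = dataclasses.replace(t_new, coefficient=0.0)
            if stripped_old != stripped_new:
                raise AssertionError(
                    f"recalibrated tier changed term structure for {t_old.name!r}"
                )
    else:
        raise AssertionError(f"updated set has unexpected tier {updated.tier!r}")
    if updated.model_name != original.model_name or updated.sex != original.sex:
        raise AssertionError("tier update must not change model identity")
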