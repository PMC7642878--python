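"""Cox absolute-risk equations: schema, loading, evaluation, horizon conversion.

A published risk score of the Framingham / China-PAR family is a sex-specific
Cox proportional-hazards model summarised by three ingredients: per-term log
hazard ratios ``beta_j``, the derivation-cohort means ``xbar_j`` of the
(transformed) covariates, and the baseline survival ``S0(t)`` at the
prediction horizon for a subject sitting at those means.  The absolute event
risk by the horizon is

    risk = 1 - S0(t) ** exp(LP - LPbar),    LP = sum_j beta_j * x_j,

with ``LPbar = sum_j beta_j * xbar_j``.  Everything a score needs is carried
in a :class:`CoefficientSet`, which is loaded from a JSON or YAML document so
that Framingham-style equations (raw continuous covariates) and
China-PAR-style equations (log transforms, age-conditional indicators) fit a
single schema.

Terms whose covariate was never measured in the validation cohort (e.g.
atrial fibrillation, parental stroke history) may be flagged
``assume_zero_if_missing``; they then contribute 0 to the linear predictor
instead of raising, mirroring how such scores are applied in practice.  The
flag is per-term and opt-in: any other missing covariate is an error.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._exceptions import DomainError, MissingCovariateError, RangeError, SchemaError

SCHEMA_VERSION = 1

TRANSFORMS = ("identity", "log", "indicator")
TIERS = ("original", "adjusted", "recalibrated")
SEXES = ("male", "female")

_CONDITION_OPS = {
    "<": np.less,
    "<=": np.less_equal,
    ">": np.greater,
    ">=": np.greater_equal,
}


@dataclass(frozen=True)
class Condition:
    """Activation condition for a conditional-indicator term.

    The term contributes only for subjects where ``covariate op value`` holds
    (e.g. diabetes counted only when ``age < 65``).
    """

    covariate: str
    op: str
    value: float

    def __post_init__(self) -> None:
        if self.op not in _CONDITION_OPS:
            raise SchemaError(
                f"condition.op must be one of {sorted(_CONDITION_OPS)}, got {self.op!r}"
            )
        if not math.isfinite(self.value):
            raise SchemaError("condition.value must be finite")

    def holds(self, values: np.ndarray) -> np.ndarray:
        return _CONDITION_OPS[self.op](values, self.value)


@dataclass(frozen=True)
class CovariateTerm:
    """One additive term ``beta * transform(x)`` of a risk equation.

    ``name`` must be unique within a coefficient set and keys the entry in
    ``covariate_means``; ``covariate`` (defaulting to ``name``) is the cohort
    column the term reads, so two conditional terms may share one column.
    """

    name: str
    coefficient: float
    transform: str = "identity"
    covariate: str | None = None
    assume_zero_if_missing: bool = False
    condition: Condition | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise SchemaError("term.name must be non-empty")
        if not math.isfinite(self.coefficient):
            raise SchemaError(f"term {self.name!r}: coefficient must be finite")
        if self.transform not in TRANSFORMS:
            raise SchemaError(
                f"term {self.name!r}: transform must be one of {TRANSFORMS}, "
                f"got {self.transform!r}"
            )
        if self.covariate is None:
            object.__setattr__(self, "covariate", self.name)

    @property
    def column(self) -> str:
        return self.covariate  # type: ignore[return-value]


@dataclass(frozen=True)
class CoefficientSet:
    """A complete absolute-risk equation for one sex at one horizon."""

    model_name: str
    sex: str
    horizon: float
    baseline_survival: float
    terms: tuple[CovariateTerm, ...]
    covariate_means: Mapping[str, float] = field(default_factory=dict)
    tier: str = "original"
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))
        object.__setattr__(self, "covariate_means", dict(self.covariate_means))
        if self.sex not in SEXES:
            raise SchemaError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.tier not in TIERS:
            raise SchemaError(f"tier must be one of {TIERS}, got {self.tier!r}")
        if not (self.horizon > 0 and math.isfinite(self.horizon)):
            raise SchemaError("horizon must be a positive, finite number of years")
        if not (0.0 < self.baseline_survival <= 1.0):
            raise SchemaError(
                f"baseline_survival must lie in (0, 1], got {self.baseline_survival}"
            )
        names = [t.name for t in self.terms]
        if len(set(names)) != len(names):
            raise SchemaError("term names must be unique within a coefficient set")
        for term in self.terms:
            if term.name not in self.covariate_means and not term.assume_zero_if_missing:
                raise SchemaError(
                    f"term {term.name!r} has no entry in covariate_means and is not "
                    "flagged assume_zero_if_missing"
                )
        for key, value in self.covariate_means.items():
            if not math.isfinite(float(value)):
                raise SchemaError(f"covariate_means[{key!r}] must be finite")

    @property
    def mean_linear_predictor(self) -> float:
        """``LPbar``: linear predictor of a subject at the covariate means."""
        return float(
            sum(t.coefficient * self.covariate_means.get(t.name, 0.0) for t in self.terms)
        )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        terms = []
        for t in self.terms:
            d: dict[str, Any] = {
                "name": t.name,
                "transform": t.transform,
                "coefficient": t.coefficient,
            }
            if t.covariate != t.name:
                d["covariate"] = t.covariate
            if t.assume_zero_if_missing:
                d["assume_zero_if_missing"] = True
            if t.condition is not None:
                d["condition"] = dataclasses.asdict(t.condition)
            terms.append(d)
        return {
            "schema_version": self.schema_version,
            "model_name": self.model_name,
            "sex": self.sex,
            "tier": self.tier,
            "horizon_years": self.horizon,
            "baseline_survival": self.baseline_survival,
            "means": dict(self.covariate_means),
            "terms": terms,
        }

    def save(self, path: str) -> None:
        doc = self.to_dict()
        with open(path, "w") as fh:
            if str(path).endswith((".yaml", ".yml")):
                yaml.safe_dump(doc, fh, sort_keys=False)
            else:
                json.dump(doc, fh, indent=2)
                fh.write("\n")


def _require(doc: Mapping[str, Any], key: str) -> Any:
    if key not in doc:
        raise SchemaError(f"missing required field {key!r}")
    return doc[key]


def coefficient_set_from_dict(doc: Mapping[str, Any]) -> CoefficientSet:
    """Build and validate a :class:`CoefficientSet` from a plain mapping."""
    if not isinstance(doc, Mapping):
        raise SchemaError("coefficient-set document must be a mapping")
    raw_terms = _require(doc, "terms")
    if not isinstance(raw_terms, Sequence) or isinstance(raw_terms, (str, bytes)):
        raise SchemaError("'terms' must be a list")
    terms = []
    for i, rt in enumerate(raw_terms):
        if not isinstance(rt, Mapping):
            raise SchemaError(f"terms[{i}] must be a mapping")
        cond = None
        if rt.get("condition") is not None:
            c = rt["condition"]
            cond = Condition(
                covariate=str(_require(c, "covariate")),
                op=str(_require(c, "op")),
                value=float(_require(c, "value")),
            )
        terms.append(
            CovariateTerm(
                name=str(_require(rt, "name")),
                coefficient=float(_require(rt, "coefficient")),
                transform=str(rt.get("transform", "identity")),
                covariate=rt.get("covariate"),
                assume_zero_if_missing=bool(rt.get("assume_zero_if_missing", False)),
                condition=cond,
            )
        )
    try:
        horizon = float(_require(doc, "horizon_years"))
        s0 = float(_require(doc, "baseline_survival"))
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"non-numeric horizon_years or baseline_survival: {exc}") from exc
    return CoefficientSet(
        model_name=str(_require(doc, "model_name")),
        sex=str(_require(doc, "sex")),
        horizon=horizon,
        baseline_survival=s0,
        terms=tuple(terms),
        covariate_means={str(k): float(v) for k, v in dict(doc.get("means", {})).items()},
        tier=str(doc.get("tier", "original")),
        schema_version=int(doc.get("schema_version", SCHEMA_VERSION)),
    )


def load_coefficient_set(source: str | Mapping[str, Any]) -> CoefficientSet:
    """Load a coefficient set from a JSON/YAML path or an in-memory mapping."""
    if isinstance(source, Mapping):
        return coefficient_set_from_dict(source)
    with open(source) as fh:
        text = fh.read()
    doc = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(doc, Mapping):
        raise SchemaError(f"{source}: document is not a mapping")
    return coefficient_set_from_dict(doc)


# -- evaluation -------------------------------------------------------------


def _as_frame(record: Mapping[str, Any] | pd.Series | pd.DataFrame) -> pd.DataFrame:
    if isinstance(record, pd.DataFrame):
        return record
    if isinstance(record, pd.Series):
        return record.to_frame().T
    return pd.DataFrame([dict(record)])


def term_values(cohort: pd.DataFrame, term: CovariateTerm) -> np.ndarray:
    """Transformed covariate values for one term, one entry per subject.

    Missing values (absent column or NaN cell) yield 0 when the term is
    flagged assume-zero, otherwise raise :class:`MissingCovariateError`.
    """
    n = len(cohort)
    if term.column not in cohort.columns:
        if term.assume_zero_if_missing:
            return np.zeros(n)
        raise MissingCovariateError(
            f"covariate {term.column!r} (term {term.name!r}) missing from cohort"
        )
    raw = pd.to_numeric(cohort[term.column], errors="coerce").to_numpy(dtype=float)
    missing = np.isnan(raw)
    if missing.any() and not term.assume_zero_if_missing:
        rows = np.flatnonzero(missing)[:5]
        raise MissingCovariateError(
            f"covariate {term.column!r} (term {term.name!r}) has missing values "
            f"at rows {rows.tolist()}"
        )
    filled = np.where(missing, 0.0, raw)
    if term.transform == "identity":
        out = filled
    elif term.transform == "log":
        bad = (~missing) & (filled <= 0)
        if bad.any():
            raise DomainError(
                f"log transform of non-positive value for covariate {term.column!r}"
            )
        out = np.where(missing, 0.0, np.log(np.where(missing, 1.0, filled)))
    else:  # indicator
        out = (filled != 0).astype(float)
        out[missing] = 0.0
    if term.condition is not None:
        cond_col = term.condition.covariate
        if cond_col not in cohort.columns:
            raise MissingCovariateError(
                f"condition covariate {cond_col!r} (term {term.name!r}) missing from cohort"
            )
        cond_vals = pd.to_numeric(cohort[cond_col], errors="coerce").to_numpy(dtype=float)
        if np.isnan(cond_vals).any():
            raise MissingCovariateError(
                f"condition covariate {cond_col!r} has missing values"
            )
        out = out * term.condition.holds(cond_vals)
    return out


def design_matrix(cohort: pd.DataFrame, terms: Iterable[CovariateTerm]) -> pd.DataFrame:
    """Per-term transformed design matrix (column per term name)."""
    cols = {t.name: term_values(cohort, t) for t in terms}
    return pd.DataFrame(cols, index=cohort.index)


def linear_predictor(
    record: Mapping[str, Any] | pd.Series | pd.DataFrame, cset: CoefficientSet
) -> float | np.ndarray:
    """``LP = sum_j beta_j * transform_j(x_j)`` for one subject or a cohort."""
    frame = _as_frame(record)
    if "sex" in frame.columns:
        sexes = set(frame["sex"].astype(str))
        if sexes - {cset.sex}:
            raise SchemaError(
                f"cohort contains sex values {sorted(sexes)} but the coefficient set "
                f"is for {cset.sex!r}; filter by sex first"
            )
    design = design_matrix(frame, cset.terms)
    beta = np.array([t.coefficient for t in cset.terms])
    lp = design.to_numpy() @ beta if len(cset.terms) else np.zeros(len(frame))
    if not isinstance(record, pd.DataFrame):
        return float(lp[0])
    return lp


def absolute_risk(lp: float | np.ndarray, cset: CoefficientSet) -> float | np.ndarray:
    """Absolute risk by the horizon, ``1 - S0 ** exp(LP - LPbar)``."""
    centered = np.asarray(lp, dtype=float) - cset.mean_linear_predictor
    risk = 1.0 - cset.baseline_survival ** np.exp(centered)
    if np.isscalar(lp) or np.ndim(lp) == 0:
        return float(risk)
    return risk


def predict_risk(cohort: pd.DataFrame, cset: CoefficientSet) -> pd.DataFrame:
    """Score a cohort: linear predictor, centered LP, and absolute risk."""
    lp = np.asarray(linear_predictor(cohort, cset), dtype=float)
    centered = lp - cset.mean_linear_predictor
    return pd.DataFrame(
        {
            "linear_predictor": lp,
            "centered_lp": centered,
            "absolute_risk": 1.0 - cset.baseline_survival ** np.exp(centered),
        },
        index=cohort.index,
    )


def convert_horizon(
    cset: CoefficientSet,
    target_horizon: float,
    baseline_curve=None,
    allow_extrapolation: bool = False,
) -> CoefficientSet:
    """Re-express a score at a different horizon.

    With a supplied baseline survival curve, ``S0(target)`` is read off the
    curve; otherwise the constant-hazard power rule
    ``S0(t') = S0(t) ** (t'/t)`` is used.  This is how a 10-year equation is
    turned into a 5-year one when only its 10-year baseline survival is known.
    """
    if not target_horizon > 0:
        raise RangeError("target_horizon must be > 0")
    if target_horizon == cset.horizon and baseline_curve is None:
        return cset
    if baseline_curve is not None:
        if target_horizon > baseline_curve.support_end and not allow_extrapolation:
            raise RangeError(
                f"target horizon {target_horizon} exceeds the curve's support "
                f"({baseline_curve.support_end}); pass allow_extrapolation=True to "
                "hold the last value"
            )
        s0 = float(baseline_curve.survival_at(target_horizon))
    else:
        s0 = float(cset.baseline_survival ** (target_horizon / cset.horizon))
    return dataclasses.replace(cset, horizon=float(target_horizon), baseline_survival=s0)
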