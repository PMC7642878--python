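"""Cohort table I/O and the end-to-end validation pipeline.

The cohort format is a delimited text file with a header, one row per
subject, an empty cell meaning "missing".  Required columns: ``id``, ``sex``
(male/female), ``follow_up_time`` (years), ``event`` (0/1).  Covariate
columns are whatever the coefficient sets reference (documented units: age in
years, sbp in mmHg, total_cholesterol and hdl_c in mg/dl, waist in cm; flags
as 0/1).

:func:`run_validation` chains everything: per sex, build the requested tiers
of each supplied model, score all subjects, and run the full battery
(KM-adjusted expected/observed events, decile Hosmer-Lemeshow chi-square,
C statistic, pairwise DeLong contrasts, continuous NRI, IDI).  The report is
written atomically: JSON plus TSV analogues of the performance and
reclassification tables and per-cell calibration-plot CSVs, only after every
stage has succeeded.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._exceptions import CoxValError
from .models import CoefficientSet, load_coefficient_set, predict_risk
from .recalibration import adjust_model, recalibrate_model
from .simulate import apply_exclusions
from .validation import (
    c_statistic,
    calibration_chi2,
    delong_compare,
    expected_vs_observed,
    reclassification,
    status_at_horizon,
)

__all__ = ["read_cohort", "write_cohort", "run_validation", "ValidationReport"]

logger = logging.getLogger("coxval")

REQUIRED_COLUMNS = ("id", "sex", "follow_up_time", "event")
TIER_ORDER = ("original", "adjusted", "recalibrated")


def read_cohort(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a cohort CSV; empty cells become missing values."""
    df = pd.read_csv(path, sep=None, engine="python")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CoxValError(f"{path}: missing required column(s) {missing}")
    errors = []
    fut = pd.to_numeric(df["follow_up_time"], errors="coerce")
    for row in df.index[fut.isna() | (fut < 0)]:
        errors.append(f"row {row + 2}: follow_up_time invalid ({df.loc[row, 'follow_up_time']!r})")
    ev = pd.to_numeric(df["event"], errors="coerce")
    for row in df.index[~ev.isin([0, 1])]:
        errors.append(f"row {row + 2}: event must be 0 or 1 ({df.loc[row, 'event']!r})")
    bad_sex = ~df["sex"].astype(str).isin(["male", "female"])
    for row in df.index[bad_sex]:
        errors.append(f"row {row + 2}: sex must be 'male' or 'female' ({df.loc[row, 'sex']!r})")
    if errors:
        raise CoxValError(f"{path}: invalid rows:\n  " + "\n  ".join(errors[:20]))
    df["follow_up_time"] = fut
    df["event"] = ev.astype(int)
    for col in df.columns:
        if col not in ("id", "sex"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    out = cohort.copy()
    for col in out.columns:
        if out[col].dtype == bool:
            out[col] = out[col].astype(int)
    out.to_csv(path, index=False)


@dataclass
class ValidationReport:
    """Everything one validation run produced, ready for serialization."""

    horizon: float
    seed: int | None
    n_input: int
    exclusion_log: dict | None
    performance: list[dict] = field(default_factory=list)  # model x sex x tier
    comparisons: list[dict] = field(default_factory=list)  # pairwise DeLong/NRI/IDI
    calibration_tables: dict = field(default_factory=dict)  # key -> DataFrame
    schema_versions: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "horizon": self.horizon,
            "seed": self.seed,
            "n_input": self.n_input,
            "exclusion_log": self.exclusion_log,
            "schema_versions": self.schema_versions,
            "performance": self.performance,
            "comparisons": self.comparisons,
        }

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        pd.DataFrame(self.performance).to_csv(out / "performance.tsv", sep="\t", index=False)
        pd.DataFrame(self.comparisons).to_csv(out / "reclassification.tsv", sep="\t", index=False)
        for key, table in self.calibration_tables.items():
            table.to_csv(out / f"calibration_{key}.csv", index=False)


def _tiered_sets(cset: CoefficientSet, cohort_sex: pd.DataFrame, tiers, horizon: float):
    out = {}
    for tier in tiers:
        if tier == "original":
            out[tier] = cset
        elif tier == "adjusted":
            out[tier] = adjust_model(cset, cohort_sex, horizon)
        elif tier == "recalibrated":
            out[tier] = recalibrate_model(cset, cohort_sex, horizon)
        else:
            raise CoxValError(f"unknown tier {tier!r}")
    return out


def run_validation(
    cohort: pd.DataFrame | str,
    models: Sequence[CoefficientSet | str],
    tiers: Sequence[str] = TIER_ORDER,
    horizon: float = 5.0,
    seed: int | None = None,
    out_dir=None,
    apply_exclusion_cascade: bool = True,
) -> ValidationReport:
    """Score a cohort with every model x tier and run the full battery.

    ``models`` may mix loaded :class:`CoefficientSet` objects and file paths;
    each supplied set is matched to subjects of its own sex.  Models sharing a
    ``model_name`` across the two sexes are treated as one sex-specific score.
    Deterministic given the inputs and seed (randomness only enters through
    optional bootstrap CIs, which use ``seed``).
    """
    t0 = time.time()
    if not isinstance(cohort, pd.DataFrame):
        cohort = read_cohort(cohort)
    if horizon <= 0:
        raise CoxValError("horizon must be > 0")
    loaded: list[CoefficientSet] = [
        m if isinstance(m, CoefficientSet) else load_coefficient_set(m) for m in models
    ]
    tiers = list(tiers)
    for tier in tiers:
        if tier not in TIER_ORDER:
            raise CoxValError(f"unknown tier {tier!r}; expected subset of {TIER_ORDER}")

    n_input = len(cohort)
    exclusion_log = None
    if apply_exclusion_cascade and {"prior_stroke", "labs_missing"} <= set(cohort.columns):
        cohort, log = apply_exclusions(cohort)
        exclusion_log = log.as_dict()
        logger.info("exclusion cascade: %s", exclusion_log)

    report = ValidationReport(
        horizon=horizon,
        seed=seed,
        n_input=n_input,
        exclusion_log=exclusion_log,
        schema_versions={m.model_name: m.schema_version for m in loaded},
    )

    for sex in ("male", "female"):
        sex_models = [m for m in loaded if m.sex == sex]
        sub = cohort[cohort["sex"] == sex]
        if not len(sub) or not sex_models:
            continue
        times = sub["follow_up_time"].to_numpy(dtype=float)
        events = sub["event"].to_numpy()
        status, include = status_at_horizon(times, events, horizon)
        n_excluded = int((~include).sum())
        scored: dict[tuple[str, str], np.ndarray] = {}
        for cset in sex_models:
            stage = time.time()
            tiered = _tiered_sets(cset, sub, tiers, horizon)
            for tier, tset in tiered.items():
                risks = predict_risk(sub, tset)["absolute_risk"].to_numpy()
                scored[(cset.model_name, tier)] = risks
                cal = calibration_chi2(risks, times, events, horizon)
                eo = expected_vs_observed(risks, times, events, horizon)
                disc = c_statistic(risks[include], status[include], n_excluded=n_excluded)
                report.performance.append(
                    {
                        "model": cset.model_name,
                        "sex": sex,
                        "tier": tier,
                        "n": len(sub),
                        "km_adjusted_events": eo.observed_events_km,
                        "predicted_events": eo.predicted_events,
                        "calibration_chi2": cal.chi2,
                        "calibration_df": cal.df,
                        "calibration_p": cal.p_value,
                        "c_statistic": disc.c_statistic,
                        "c_ci_lower": disc.ci_lower,
                        "c_ci_upper": disc.ci_upper,
                        "n_censored_excluded": disc.n_excluded,
                        "baseline_survival": tset.baseline_survival,
                    }
                )
                report.calibration_tables[f"{cset.model_name}_{tier}_{sex}"] = cal.table
            logger.info("scored %s (%s) in %.2fs", cset.model_name, sex, time.time() - stage)

        # pairwise contrasts: between models within a tier, and original vs
        # recalibrated within a model
        pairs = []
        names = [m.model_name for m in sex_models]
        for tier in tiers:
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    pairs.append(((names[i], tier), (names[j], tier)))
        if "original" in tiers and "recalibrated" in tiers:
            for name in names:
                pairs.append(((name, "original"), (name, "recalibrated")))
        for key_a, key_b in pairs:
            ra, rb = scored[key_a], scored[key_b]
            dl = delong_compare(ra[include], rb[include], status[include])
            rec = reclassification(ra[include], rb[include], status[include],
                                   n_excluded=n_excluded)
            report.comparisons.append(
                {
                    "sex": sex,
                    "old_model": key_a[0], "old_tier": key_a[1],
                    "new_model": key_b[0], "new_tier": key_b[1],
                    "delta_c": dl.delta_c,
                    "delta_c_ci_lower": dl.ci_lower,
                    "delta_c_ci_upper": dl.ci_upper,
                    "delta_c_p": dl.p_value,
                    "events_up": rec.events_up, "events_down": rec.events_down,
                    "nonevents_up": rec.nonevents_up, "nonevents_down": rec.nonevents_down,
                    "event_nri": rec.event_nri, "nonevent_nri": rec.nonevent_nri,
                    "total_nri": rec.total_nri,
                    "nri_ci_lower": rec.nri_ci[0], "nri_ci_upper": rec.nri_ci[1],
                    "idi": rec.idi,
                    "idi_ci_lower": rec.idi_ci[0], "idi_ci_upper": rec.idi_ci[1],
                }
            )

    logger.info("validation complete in %.2fs", time.time() - t0)
    if out_dir is not None:
        report.write(out_dir)
    return report
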