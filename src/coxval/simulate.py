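"""Synthetic validation cohorts with known ground truth.

The generator emulates a community cohort of older Chinese adults of the kind
used to externally validate stroke risk scores: ~2,500 subjects aged 55+,
sex-specific covariate marginals (blood pressure, lipids, waist circumference,
treatment/comorbidity prevalences), stroke-like event times from a Cox model
with a constant baseline hazard, administrative censoring at the mean
follow-up with a uniform early-dropout fraction, and the pre-analysis
exclusion cascade (prior stroke, over-age, missing laboratory data) that
reduces the raw sample to the analysis set.

Because the generating model is known exactly, every downstream stage can be
tested against truth: the original tier is perfectly calibrated when the
evaluated score equals the truth, and :func:`miscalibration_scenarios`
perturbs exactly one ingredient (means, baseline survival, or coefficients)
to exercise the repair each updating tier is supposed to deliver.

Covariates are drawn independently (the emulated study reports only
marginals); continuous ones as truncated normals, flags as Bernoulli.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import CoefficientSet, CovariateTerm

__all__ = [
    "ContinuousSpec",
    "SexProfile",
    "SimulationConfig",
    "ExclusionLog",
    "default_config",
    "default_true_model",
    "true_model_as_coefficient_set",
    "generate_cohort",
    "apply_exclusions",
    "miscalibration_scenarios",
]

SCENARIOS = ("none", "shifted-means", "wrong-baseline-survival", "wrong-coefficients")


@dataclass(frozen=True)
class ContinuousSpec:
    """Truncated-normal marginal for a continuous covariate."""

    mean: float
    sd: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("infeasible truncation bounds: lower must be < upper")
        if self.sd <= 0:
            raise ValueError("sd must be positive")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        a = (self.lower - self.mean) / self.sd
        b = (self.upper - self.mean) / self.sd
        return stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=n, random_state=rng)


@dataclass(frozen=True)
class SexProfile:
    """Per-sex covariate marginals (means/SDs and prevalences)."""

    age: ContinuousSpec
    sbp: ContinuousSpec
    total_cholesterol: ContinuousSpec
    hdl_c: ContinuousSpec
    waist: ContinuousSpec
    prevalence: dict = field(default_factory=dict)  # flag name -> probability

    def __post_init__(self) -> None:
        for name, p in self.prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence[{name!r}] must lie in [0, 1]")


def _age_location(target_mean: float, sd: float, lo: float = 55.0, hi: float = 84.0) -> float:
    """Underlying normal location whose [lo, hi]-truncated mean equals the target.

    The reported age moments describe the analysis window (55-84), but ages
    are drawn on a wider upper window so the over-age exclusion is
    non-trivial; this back-solves the pre-truncation location.
    """
    from scipy.optimize import brentq

    def trunc_mean(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - target_mean

    return float(brentq(trunc_mean, target_mean - 3 * sd, target_mean + 3 * sd))


# Sex-specific marginals of the emulated analysis population (ages 55-84 at
# analysis; age is drawn on a wider upper window so the over-age exclusion is
# non-trivial).  Units: years, mmHg, mg/dl, cm.
MALE_PROFILE = SexProfile(
    age=ContinuousSpec(_age_location(69.21, 7.73), 7.73, 55.0, 95.0),
    sbp=ContinuousSpec(138.18, 19.58, 80.0, 230.0),
    total_cholesterol=ContinuousSpec(214.48, 39.01, 90.0, 420.0),
    hdl_c=ContinuousSpec(46.72, 10.99, 15.0, 110.0),
    waist=ContinuousSpec(88.94, 9.73, 55.0, 140.0),
    prevalence={
        "urban": 0.674,
        "antihypertensive": 0.318,
        "diabetes": 0.136,
        "smoking": 0.458,
        "cvd_history": 0.143,
    },
)

FEMALE_PROFILE = SexProfile(
    age=ContinuousSpec(_age_location(68.15, 7.49), 7.49, 55.0, 95.0),
    sbp=ContinuousSpec(139.17, 20.31, 80.0, 230.0),
    total_cholesterol=ContinuousSpec(237.91, 45.24, 90.0, 420.0),
    hdl_c=ContinuousSpec(47.90, 10.24, 15.0, 110.0),
    waist=ContinuousSpec(91.08, 10.69, 55.0, 140.0),
    prevalence={
        "urban": 0.658,
        "antihypertensive": 0.440,
        "diabetes": 0.182,
        "smoking": 0.075,
        "cvd_history": 0.165,
    },
)

# Shared synthetic log hazard ratios for the true generating model (per
# transformed unit: years, mmHg, mg/dl; indicators are 0/1).
_TRUE_BETA = {
    "age": 0.055,
    "sbp": 0.012,
    "total_cholesterol": 0.0015,
    "hdl_c": -0.018,
    "smoking": 0.40,
    "diabetes": 0.45,
    "antihypertensive": 0.25,
    "cvd_history": 0.35,
}

# Constant baseline hazards (events per person-year at the covariate means),
# set so that the default analysis cohort of ~1,200 subjects followed a mean
# ~5 years accrues roughly 105 strokes, slightly more often in men than women.
_BASELINE_HAZARD = {"male": 0.0172, "female": 0.0155}


def default_true_model(sex: str, horizon: float = 5.0) -> CoefficientSet:
    """The synthetic 'published' risk equation for one sex.

    Its covariate means are the generator's marginal means for that sex and
    its baseline survival is exp(-lambda * horizon) for the generator's
    constant baseline hazard, so that under the default configuration the
    score is exactly calibrated to the cohorts it is applied to.
    """
    profile = MALE_PROFILE if sex == "male" else FEMALE_PROFILE
    terms = tuple(
        CovariateTerm(
            name=name,
            coefficient=beta,
            transform="identity" if name in ("age", "sbp", "total_cholesterol", "hdl_c") else "indicator",
        )
        for name, beta in _TRUE_BETA.items()
    )
    means = {
        "age": profile.age.mean,
        "sbp": profile.sbp.mean,
        "total_cholesterol": profile.total_cholesterol.mean,
        "hdl_c": profile.hdl_c.mean,
        "smoking": profile.prevalence["smoking"],
        "diabetes": profile.prevalence["diabetes"],
        "antihypertensive": profile.prevalence["antihypertensive"],
        "cvd_history": profile.prevalence["cvd_history"],
    }
    s0 = float(np.exp(-_BASELINE_HAZARD[sex] * horizon))
    return CoefficientSet(
        model_name="synthetic-stroke-score",
        sex=sex,
        horizon=float(horizon),
        baseline_survival=s0,
        terms=terms,
        covariate_means=means,
        tier="original",
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of a synthetic validation cohort.

    Event times follow a proportional-hazards model with cumulative hazard
    ``H(t) = (lambda t)^shape * exp(LP - LPbar)`` where ``LPbar`` centres at
    the true model's covariate means (``shape = 1`` gives the default
    exponential).  Censoring is administrative at ``admin_censor_years`` with
    a ``dropout_fraction`` of subjects censored uniformly earlier.
    """

    n_total: int = 2468
    male_fraction: float = 537.0 / 1203.0
    profiles: dict = field(
        default_factory=lambda: {"male": MALE_PROFILE, "female": FEMALE_PROFILE}
    )
    true_models: dict = field(
        default_factory=lambda: {s: default_true_model(s) for s in ("male", "female")}
    )
    baseline_hazard: dict = field(default_factory=lambda: dict(_BASELINE_HAZARD))
    weibull_shape: float = 1.0
    admin_censor_years: float = 5.1
    dropout_fraction: float = 0.125
    prior_stroke_fraction: float = 297.0 / 2468.0
    missing_labs_fraction: float = 815.0 / 2018.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        for name in ("male_fraction", "dropout_fraction", "prior_stroke_fraction",
                     "missing_labs_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if min(self.baseline_hazard.values()) < 0:
            raise ValueError("baseline hazards must be >= 0")
        if self.weibull_shape <= 0:
            raise ValueError("weibull_shape must be positive")
        if self.admin_censor_years <= 0:
            raise ValueError("admin_censor_years must be positive")


def default_config(**overrides) -> SimulationConfig:
    """The study-condition defaults, optionally overridden field-by-field."""
    return dataclasses.replace(SimulationConfig(), **overrides) if overrides else SimulationConfig()


def true_model_as_coefficient_set(
    config: SimulationConfig, sex: str, horizon: float
) -> CoefficientSet:
    """The generating truth expressed as an evaluable risk equation.

    Baseline survival at the horizon is the generator's own
    ``exp(-(lambda t)^shape)``; covariate means are those the generator
    centres the hazard at.  Scoring a generated cohort with this set yields
    each subject's true event probability by the horizon.
    """
    tm = config.true_models[sex]
    lam = config.baseline_hazard[sex]
    s0 = float(np.exp(-((lam * horizon) ** config.weibull_shape)))
    return dataclasses.replace(tm, horizon=float(horizon), baseline_survival=s0)


def _draw_sex_block(
    sex: str, n: int, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    profile: SexProfile = config.profiles[sex]
    df = pd.DataFrame(
        {
            "sex": sex,
            "age": profile.age.draw(n, rng),
            "sbp": profile.sbp.draw(n, rng),
            "total_cholesterol": profile.total_cholesterol.draw(n, rng),
            "hdl_c": profile.hdl_c.draw(n, rng),
            "waist": profile.waist.draw(n, rng),
        }
    )
    for flag, p in profile.prevalence.items():
        df[flag] = rng.random(n) < p
    df["prior_stroke"] = rng.random(n) < config.prior_stroke_fraction
    df["labs_missing"] = rng.random(n) < config.missing_labs_fraction

    tm = config.true_models[sex]
    from .models import linear_predictor  # local import avoids cycle at module load

    lp = np.asarray(linear_predictor(df, tm), dtype=float)
    lpc = lp - tm.mean_linear_predictor
    lam = config.baseline_hazard[sex]
    shape = config.weibull_shape
    # T solves (lam T)^shape * exp(lpc) = E,  E ~ Exp(1)
    e_std = rng.exponential(1.0, n)
    event_time = (e_std / np.exp(lpc)) ** (1.0 / shape) / lam
    censor = np.full(n, config.admin_censor_years)
    dropout = rng.random(n) < config.dropout_fraction
    censor[dropout] = rng.uniform(0.0, config.admin_censor_years, int(dropout.sum()))
    df["follow_up_time"] = np.minimum(event_time, censor)
    df["event"] = event_time <= censor
    return df


def generate_cohort(config: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw a full (pre-exclusion) cohort; deterministic for a fixed seed."""
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n_male = int(round(config.n_total * config.male_fraction))
    blocks = []
    for sex, n in (("male", n_male), ("female", config.n_total - n_male)):
        if n > 0:
            blocks.append(_draw_sex_block(sex, n, config, rng))
    cohort = pd.concat(blocks, ignore_index=True)
    cohort.insert(0, "id", np.arange(1, len(cohort) + 1))
    return cohort


@dataclass(frozen=True)
class ExclusionLog:
    """Per-rule exclusion counts; each subject counted once, first matching rule."""

    n_input: int
    prior_stroke: int
    over_age: int
    missing_labs: int
    n_analysis: int

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def apply_exclusions(
    cohort: pd.DataFrame, age_min: float = 55.0, age_max: float = 84.0
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the pre-analysis exclusion cascade.

    Rules in order: history of stroke, age outside [age_min, age_max],
    missing laboratory data.  A subject is counted under the first rule it
    violates.  Idempotent: re-applying to the analysis cohort removes nobody.
    """
    prior = cohort["prior_stroke"].astype(bool).to_numpy()
    age = cohort["age"].to_numpy(dtype=float)
    over = (~prior) & ((age > age_max) | (age < age_min))
    labs = (~prior) & (~over) & cohort["labs_missing"].astype(bool).to_numpy()
    keep = ~(prior | over | labs)
    log = ExclusionLog(
        n_input=len(cohort),
        prior_stroke=int(prior.sum()),
        over_age=int(over.sum()),
        missing_labs=int(labs.sum()),
        n_analysis=int(keep.sum()),
    )
    return cohort.loc[keep].reset_index(drop=True), log


def miscalibration_scenarios(config: SimulationConfig, scenario: str) -> SimulationConfig:
    """Perturb the generating truth in exactly one named component.

    The evaluated score (e.g. ``default_true_model``) is left untouched by
    construction; the returned config makes the *cohort* deviate from it:

    * ``shifted-means`` — the truth centres its hazard at shifted covariate
      means (older, higher blood pressure), so the evaluated score's means are
      wrong for the cohort; repaired by the adjusted tier.
    * ``wrong-baseline-survival`` — the baseline hazard is doubled, so the
      evaluated score's baseline survival is too optimistic; repaired by the
      adjusted tier.
    * ``wrong-coefficients`` — the truth re-weights the risk factors (blood
      pressure and comorbidities dominate instead of age), so the evaluated
      score mis-ranks subjects; repaired only by the recalibrated tier.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    if scenario == "none":
        return config
    if scenario == "wrong-baseline-survival":
        hazards = {s: 2.0 * lam for s, lam in config.baseline_hazard.items()}
        return dataclasses.replace(config, baseline_hazard=hazards)
    if scenario == "shifted-means":
        new_models = {}
        for sex, tm in config.true_models.items():
            means = dict(tm.covariate_means)
            means["age"] = means["age"] - 4.0
            means["sbp"] = means["sbp"] - 12.0
            new_models[sex] = dataclasses.replace(tm, covariate_means=means)
        return dataclasses.replace(config, true_models=new_models)
    # wrong-coefficients: same covariates, very different weighting
    perturbed = {
        "age": 0.015,
        "sbp": 0.030,
        "total_cholesterol": 0.0,
        "hdl_c": -0.050,
        "smoking": 1.10,
        "diabetes": 1.20,
        "antihypertensive": 0.0,
        "cvd_history": 0.90,
    }
    new_models = {}
    for sex, tm in config.true_models.items():
        terms = tuple(
            dataclasses.replace(t, coefficient=perturbed[t.name]) for t in tm.terms
        )
        new_models[sex] = dataclasses.replace(tm, terms=terms)
    return dataclasses.replace(config, true_models=new_models)
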