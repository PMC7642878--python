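import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from coxval import CoefficientSet, CovariateTerm, generate_cohort
from coxval.simulate import default_config, true_model_as_coefficient_set

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
    deadline=None,
)
settings.load_profile("ci")

HORIZON = 5.0


@pytest.fixture
def simple_set() -> CoefficientSet:
    """A two-term score with easy hand arithmetic."""
    return CoefficientSet(
        model_name="toy",
        sex="male",
        horizon=5.0,
        baseline_survival=0.95,
        terms=(
            CovariateTerm(name="x", coefficient=0.5),
            CovariateTerm(name="flag", coefficient=0.7, transform="indicator"),
        ),
        covariate_means={"x": 2.0, "flag": 0.3},
    )


@pytest.fixture(scope="session")
def null_config():
    """Single-sex study-free config: no exclusions, evaluated score == truth."""
    return default_config(
        n_total=2000,
        male_fraction=1.0,
        prior_stroke_fraction=0.0,
        missing_labs_fraction=0.0,
    )


@pytest.fixture(scope="session")
def null_cohort(null_config):
    return generate_cohort(null_config, seed=101)


@pytest.fixture(scope="session")
def null_truth(null_config):
    return true_model_as_coefficient_set(null_config, "male", HORIZON)


@pytest.fixture(scope="session")
def two_group_exponential():
    """n=2000 two-arm exponential survival with true hazard ratio 2."""
    rng = np.random.default_rng(7)
    n = 2000
    x = (rng.random(n) < 0.5).astype(float)
    t = rng.exponential(1.0 / (0.1 * np.exp(np.log(2.0) * x)))
    c = rng.uniform(0, 15, n)
    return pd.DataFrame(
        {"x": x, "time": np.minimum(t, c), "event": (t <= c).astype(int)}
    )
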