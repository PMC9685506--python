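import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from driftgbm import evaluation, features, sampler, synthetic, transfer

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> synthetic.CohortConfig:
    """Three-year desk-scale cohort with moderate drift."""
    return synthetic.drift_scenario(
        n_per_year=300, years=(2010, 2011, 2017), seed=11
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return synthetic.generate_cohort(small_config, 2010)


@pytest.fixture(scope="session")
def small_records(small_cohort) -> pd.DataFrame:
    return pd.concat([t.to_records() for t in small_cohort], ignore_index=True)


@pytest.fixture(scope="session")
def small_scheme(small_records) -> features.FeatureScheme:
    return features.fit_scheme(small_records)


@pytest.fixture(scope="session")
def small_matrix(small_cohort, small_scheme) -> sampler.SampleMatrix:
    return sampler.assemble_matrix(
        small_cohort, None, sampler.TaskSpec.any_aki(), small_scheme
    )


@pytest.fixture(scope="session")
def toy_xy():
    """Small two-feature learnable classification frame."""
    rng = np.random.default_rng(5)
    X = pd.DataFrame(rng.normal(size=(300, 2)), columns=["f0", "f1"])
    y = (X["f0"].to_numpy() + 0.5 * rng.normal(size=300) > 0).astype(int)
    return X, y


# ---------------------------------------------------------------------------
# session-scoped stochastic regime runs, shared by the acceptance tests

from helpers import run_strategies, run_trend  # noqa: E402

DOMINANCE_SEEDS = tuple(range(20))
DEGRADATION_SEEDS = tuple(range(10))
TREND_SEEDS = tuple(range(20))


@pytest.fixture(scope="session")
def dominance_runs():
    """Moderate-drift scenario at both training fractions, 20 seeds."""
    out = {}
    for fraction in (0.25, 1.0):
        per_seed = []
        for seed in DOMINANCE_SEEDS:
            res = run_strategies(seed, fraction=fraction)
            per_seed.append(
                {k: evaluation.auroc(p, res["y"]) for k, p in res["p"].items()}
            )
        out[fraction] = per_seed
    return out


@pytest.fixture(scope="session")
def zero_drift_runs():
    """Stationary world: no covariate or concept drift."""
    kw = {"concept_drift_rate": 0.0, "covariate_shift_rate": 0.0}
    return [
        run_strategies(seed, n_per_year=1000, drift_kwargs=kw)
        for seed in DEGRADATION_SEEDS
    ]


@pytest.fixture(scope="session")
def rerandomized_runs():
    """Abrupt complete concept change in the target year."""
    kw = {"rerandomize_from_year": 2012}
    return [
        run_strategies(
            seed, years=(2010, 2011, 2012), n_per_year=1000, drift_kwargs=kw
        )
        for seed in DEGRADATION_SEEDS
    ]


@pytest.fixture(scope="session")
def trend_runs():
    return [run_trend(seed) for seed in TREND_SEEDS]
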