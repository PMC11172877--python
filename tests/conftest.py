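import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_survival():
    """Six-sample survival frame with distinct times and mixed censoring."""
    return pd.DataFrame(
        {
            "time_months": [3.0, 7.0, 9.0, 14.0, 20.0, 31.0],
            "event": [1, 1, 0, 1, 0, 1],
        },
        index=pd.Index([f"s{i}" for i in range(1, 7)], name="sample_id"),
    )


@pytest.fixture
def templates():
    from bcplast.simulate import synthetic_templates

    return synthetic_templates(seed=7)


@pytest.fixture
def centroids():
    from bcplast.simulate import synthetic_centroids

    return synthetic_centroids(seed=11)


@pytest.fixture
def survival_cohort():
    """The standard planted-signal cohort used across recovery tests."""
    from bcplast.simulate import simulate_survival_cohort

    return simulate_survival_cohort(
        n_samples=100, n_genes=300, n_planted=20, hazard_ratio=4.0,
        censoring_fraction=0.3, seed=42,
    )


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
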