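import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def covariate_table():
    """Small raw covariate table: 6 units, 2 plain columns + elevation."""
    return pd.DataFrame(
        {
            "unit_id": [f"u{j}" for j in range(1, 7)],
            "soil": [2.0, 4.0, 6.0, 3.0, 5.0, 1.0],
            "forest": [10.0, 20.0, 15.0, 40.0, 5.0, 30.0],
            "mean_elevation": [100.0, 399.0, 400.0, 1200.0, 50.0, 700.0],
        }
    )


@pytest.fixture
def climate_table(rng):
    """20 units x 24 monthly climate columns with correlated structure."""
    from abundsel.covariate_prep import CLIMATE_COLUMNS

    J = 20
    lat = rng.normal(size=J)
    cont = rng.normal(size=J)
    data = {"unit_id": [f"u{j}" for j in range(J)]}
    for m, name in enumerate(CLIMATE_COLUMNS):
        season = np.cos(2 * np.pi * (m % 12) / 12)
        base = lat * (1 + 0.5 * season) if name.startswith("temp") else cont - 0.3 * lat
        data[name] = 10 + 3 * base + rng.normal(scale=0.5, size=J)
    return pd.DataFrame(data)


@pytest.fixture(scope="session")
def tiny_survey():
    """Small simulated survey (J=60, I=3, R=3, one active effect)."""
    from abundsel import ScenarioSpec, generate_covariates, simulate_survey

    spec = ScenarioSpec(
        J=60, I=3, R=3, seed=77, active_set=(0,), true_beta=(0.8,), true_tau=25.0
    )
    X = generate_covariates(spec.J, spec.R, spec.covariate_correlation, spec.seed)
    data, truth_obs, truth_sel = simulate_survey(spec, X)
    return spec, X, data, truth_obs, truth_sel
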