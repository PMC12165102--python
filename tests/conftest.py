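import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

import nutrigeom as ng


@pytest.fixture(scope="session")
def apex_design():
    return ng.make_apex_diets()


@pytest.fixture(scope="session")
def full_design():
    return ng.make_full_design(10, seed=1)


@pytest.fixture(scope="session")
def treg_table():
    """Default fat-dominant linear-truth feeding experiment (seed 7)."""
    table, beta = ng.gen_treg_experiment(ng.TregConfig(seed=7))
    return table, beta


@pytest.fixture(scope="session")
def small_panel():
    """A reduced country panel for fast GAMM unit tests."""
    cfg = ng.PanelConfig(n_countries=40, year_start=2000, year_end=2015, seed=11)
    return ng.gen_country_panel(cfg)


@pytest.fixture(scope="session")
def default_panel():
    """The full-scale default panel (150 countries x 29 years), seed 11."""
    return ng.gen_country_panel(ng.PanelConfig(seed=11))


def normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Independent least-squares oracle: explicit (X'X)^-1 X'y."""
    return np.linalg.solve(X.T @ X, X.T @ y)
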