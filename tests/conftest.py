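import numpy as np
import pandas as pd
import pytest

from healthcast import GeneratorConfig, generate_panel


@pytest.fixture(scope="session")
def world_config() -> GeneratorConfig:
    return GeneratorConfig(n_countries=20, seed=42)


@pytest.fixture(scope="session")
def world(world_config) -> pd.DataFrame:
    """A 20-country synthetic panel shared across tests."""
    return generate_panel(world_config)


@pytest.fixture(scope="session")
def big_world() -> pd.DataFrame:
    """Full-size synthetic world (188 countries x 21 years)."""
    return generate_panel(GeneratorConfig(seed=2024))


def make_tiny_panel(n_countries=2, n_years=3, seed=0) -> pd.DataFrame:
    """A minimal hand-sized panel with all invariants satisfied."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_countries):
        gdp = 1000.0 * (i + 1)
        for t in range(n_years):
            rows.append(
                {
                    "country_id": f"X{i}",
                    "year": 2000 + t,
                    "gdp_pc": gdp * (1.02**t),
                    "gov_spend": 3e8 * (i + 1),
                    "ghes_pc": 50.0 + i,
                    "ppp_pc": 10.0,
                    "oop_pc": 20.0,
                    "dah_pc": 5.0,
                    "population": 1e6 * (i + 1),
                    "uhc_index": 50.0 + 5 * i + t + rng.uniform(0, 0.1),
                    "income_group": "low" if i % 2 == 0 else "high",
                    "super_region": "south_asia",
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def tiny_panel() -> pd.DataFrame:
    return make_tiny_panel()
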