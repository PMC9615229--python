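import numpy as np
import pandas as pd
import pytest

from ecosir.data_io import Dataset, RunConfig
from ecosir.synthetic_data import SimulationSpec, simulate_dataset


@pytest.fixture
def tiny_config() -> RunConfig:
    return RunConfig(
        birth_years=(1990, 1995),
        study_end_year=2005,
        census_period_map={1988: (1990, 1992), 2000: (1993, 1995)},
    )


@pytest.fixture
def tiny_dataset() -> Dataset:
    """Three municipalities, one case: the smallest valid dataset."""
    municipalities = pd.DataFrame(
        {
            "municipality_id": ["A", "B", "C"],
            "area_km2": [10.0, 20.0, 5.0],
            "urban_unit_class": ["other_uu", "paris_uu", "other_uu"],
            "uv_class": ["high", "low", "low"],
            "deprivation_class": ["Q1_Q4", "Q1_Q4", "Q5_most_deprived"],
            "population_size_class": ["uu_le_100k", "uu_gt_100k", "uu_le_100k"],
        }
    )
    censuses = pd.DataFrame(
        {
            "municipality_id": ["A", "A", "B", "C"],
            "census_year": [1988, 1988, 1988, 2000],
            "crop_type": ["total", "viticulture", "total", "total"],
            "crop_area_km2": [5.0, 2.0, 0.0, 4.0],
        }
    )
    births = pd.DataFrame(
        {
            "municipality_id": ["A", "A", "B", "C"],
            "birth_year": [1990, 1991, 1990, 1993],
            "n_births": [100, 120, 500, 50],
        }
    )
    cases = pd.DataFrame(
        {
            "municipality_id": ["A"],
            "birth_year": [1990],
            "age_at_diagnosis": [3],
            "subtype": ["BCP_ALL"],
        }
    )
    return Dataset(municipalities, censuses, births, cases)


@pytest.fixture(scope="session")
def desk_spec() -> SimulationSpec:
    """A small but structurally complete simulation for fast tests."""
    return SimulationSpec(seed=42, n_municipalities=500, mean_births=40.0)


@pytest.fixture(scope="session")
def desk_simulation(desk_spec):
    return simulate_dataset(desk_spec)


@pytest.fixture(scope="session")
def desk_dataset(desk_simulation):
    return desk_simulation[0]


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
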