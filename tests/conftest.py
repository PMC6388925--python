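import numpy as np
import pandas as pd
import pytest

from posdev.io_config import CANONICAL_COLUMNS, PipelineConfig
from posdev.synthetic_data import SyntheticSpec, generate_households


def make_table(n: int = 12, seed: int = 0) -> pd.DataFrame:
    """Small hand-rolled valid household table (independent of the generator)."""
    rng = np.random.default_rng(seed)
    villages = [f"V{i % 4}" for i in range(n)]
    regions = {0: "north", 1: "north", 2: "south", 3: "south"}
    return pd.DataFrame(
        {
            "household_id": [f"H{i:03d}" for i in range(n)],
            "village_id": villages,
            "region": [regions[i % 4] for i in range(n)],
            "mae": rng.uniform(1.5, 7, n).round(2),
            "household_type": ["couple"] * (n - 2) + ["single_woman", "single_man"],
            "land_ha": rng.uniform(0.2, 9, n).round(2),
            "livestock_tlu": np.where(rng.random(n) < 0.5, 0.0, rng.uniform(0.1, 3, n)).round(2),
            "crop_diversity": rng.integers(1, 8, n),
            "livestock_diversity": rng.integers(0, 4, n),
            "market_orientation": rng.uniform(0, 1, n).round(3),
            # straddle a 2550 kcal requirement so capped sufficiency varies
            "food_availability": np.concatenate(
                [rng.uniform(900, 2300, n // 2), rng.uniform(2600, 5000, n - n // 2)]
            ).round(0),
            "food_insecure_months": rng.integers(0, 7, n),
            "hdds_good": rng.integers(3, 12, n),
            "hdds_lean": rng.integers(1, 9, n),
            "farm_income": rng.uniform(0, 2000, n).round(1),
            "offfarm_income": rng.uniform(0, 800, n).round(1),
            "ghg_emissions": rng.uniform(10, 3000, n).round(1),
            "female_share": rng.uniform(0.1, 0.8, n).round(3),
            "male_share": 0.0,
        }
    ).assign(male_share=lambda d: (1 - d["female_share"] - 0.02).round(3))[CANONICAL_COLUMNS]


@pytest.fixture
def small_table() -> pd.DataFrame:
    return make_table()


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def survey_500():
    """One moderately sized synthetic survey shared across tests."""
    spec = SyntheticSpec(n_households=500, seed=11)
    records, truth = generate_households(spec)
    return records, truth
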