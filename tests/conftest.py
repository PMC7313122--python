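import numpy as np
import pandas as pd
import pytest

from qutece_bbb.phantom import PhantomConfig, RegionParams, generate_atlas
from qutece_bbb.volumes import RegionTable


@pytest.fixture(scope="session")
def toy_region_table() -> RegionTable:
    """Eight-region lookup table for small, fast phantoms."""
    return RegionTable(
        pd.DataFrame(
            {
                "region_id": np.arange(1, 9),
                "region_name": [f"region {i}" for i in range(1, 9)],
            }
        )
    )


@pytest.fixture(scope="session")
def toy_params() -> list[RegionParams]:
    """Generative parameters with a strong group effect in half the regions."""
    params = []
    for rid in range(1, 9):
        affected = rid <= 4
        params.append(
            RegionParams(
                region_id=rid,
                control_mode_mean=0.03,
                control_mode_sd=0.01,
                diabetic_mode_mean=0.10 if affected else 0.03,
                diabetic_mode_sd=0.01,
            )
        )
    return params


@pytest.fixture(scope="session")
def toy_config() -> PhantomConfig:
    # 4 vs 4: the smallest exact two-sided p (2/70) can cross alpha = 0.05,
    # unlike 3 vs 3 whose floor is 0.1
    return PhantomConfig(grid_shape=(24, 24, 24), n_control=4, n_diabetic=4, rng_seed=42)


@pytest.fixture(scope="session")
def toy_atlas(toy_config, toy_region_table):
    return generate_atlas(toy_config, toy_region_table)
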