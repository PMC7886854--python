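import numpy as np
import pandas as pd
import pytest

from esdm import synthetic_world as sw
from esdm.niche_sampling import build_niche_dataset


@pytest.fixture(scope="session")
def grid():
    return sw.default_grid()


@pytest.fixture(scope="session")
def stack(grid):
    return sw.generate_contemporary_stack(grid, seed=1)


@pytest.fixture(scope="session")
def niche():
    return sw.TrueNiche(
        mu={"SBT": 15.0, "SBTrange": 6.0},
        sigma={"SBT": 3.0, "SBTrange": 3.0},
        s_max=0.9,
    )


@pytest.fixture(scope="session")
def occurrences(stack, niche):
    return sw.sample_occurrences(stack, niche, 500, seed=2)


def env_frame(stack, cells, factors):
    """Environment table (factor columns + cell id) at flat cell ids."""
    X = stack.env_at_cells(cells, factors)
    df = pd.DataFrame(X, columns=list(factors))
    df["cell"] = np.asarray(cells)
    return df.dropna().reset_index(drop=True)


@pytest.fixture(scope="session")
def presence_env(stack, occurrences, grid):
    from esdm.occurrence_pipeline import clean_records, grid_occurrences

    kept, _ = clean_records(
        occurrences, grid,
        land_mask=~stack.ocean_mask,
        bathymetry=np.nan_to_num(stack.factors["bathymetry"], nan=0.0),
    )
    occ_set = grid_occurrences(kept, grid)
    return env_frame(stack, occ_set.cells, ("SBT", "SBTrange"))


@pytest.fixture(scope="session")
def background_env(stack):
    cells = stack.ocean_cells
    return env_frame(stack, cells, ("SBT", "SBTrange"))


@pytest.fixture(scope="session")
def dataset(presence_env, background_env):
    return build_niche_dataset(
        presence_env, background_env, ("SBT", "SBTrange"), q=(10.0, 90.0), seed=3
    )
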