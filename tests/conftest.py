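import numpy as np
import pytest

from bioscape.geodata_io import GridSpec, RunConfig
from bioscape.landuse_harmonizer import harmonize
from bioscape.msa_model import MSAParams
from bioscape.synthetic_landscape import generate_landscape, generate_species


def make_grid(n: int = 16, cell: float = 100.0) -> GridSpec:
    return GridSpec(n_rows=n, n_cols=n, cell_size=cell, origin_x=0.0, origin_y=n * cell)


@pytest.fixture(scope="session")
def grid64() -> GridSpec:
    return make_grid(64)


@pytest.fixture(scope="session")
def bundle(grid64):
    return generate_landscape(seed=7, grid=grid64, n_roads=4, n_departments=6)


@pytest.fixture(scope="session")
def cfg(grid64):
    return RunConfig(
        seed=7,
        grid=grid64,
        pasture_area_budget_ha=400.0,
        national_production_t=50_000.0,
        flii_threshold=6.0,
    )


@pytest.fixture(scope="session")
def landuse(bundle, cfg):
    return harmonize(bundle, cfg)


@pytest.fixture(scope="session")
def params() -> MSAParams:
    return MSAParams()


@pytest.fixture(scope="session")
def species(bundle, grid64):
    return generate_species(seed=11, n_species=25, grid=grid64, dem=bundle.dem)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
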