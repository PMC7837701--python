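import numpy as np
import pandas as pd
import pytest

from scatlas import (
    AtlasModel,
    AtlasSimSpec,
    ClassSpec,
    PipelineConfig,
    simulate_atlas,
)
from scatlas.preprocess import normalize_log, scale_genes, select_hvgs


@pytest.fixture(scope="session")
def small_spec():
    return AtlasSimSpec(
        n_genes=800,
        classes=[ClassSpec(f"C{i}", n_types=2) for i in range(4)],
        n_cells=1200,
        seed=1,
    )


@pytest.fixture(scope="session")
def small_sim(small_spec):
    return simulate_atlas(small_spec)


@pytest.fixture(scope="session")
def small_nm(small_sim):
    cm, _ = small_sim
    nm = normalize_log(cm)
    select_hvgs(nm, n_hvgs=500)
    scale_genes(nm)
    return nm


@pytest.fixture(scope="session")
def small_config():
    return PipelineConfig(min_genes_per_cell=0, n_hvgs=500, rng_seed=1)


@pytest.fixture(scope="session")
def fitted_small(small_spec, small_config):
    model = AtlasModel.from_simulation(small_spec, config=small_config)
    res = model.fit()
    return model, res


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
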