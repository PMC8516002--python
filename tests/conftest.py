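"""Shared fixtures: a small synthetic atlas reused across test modules."""

import numpy as np
import pytest

from rootatlas import preprocess as pp
from rootatlas import simulate as sim


@pytest.fixture(scope="session")
def small_config():
    return sim.SimConfig(
        n_types=3, n_stages=4, n_genes=600, markers_per_type=15,
        stage_genes_per_type=10, hs_program_size=30, n_cells=300,
        marker_fold=8.0, seed=7,
    )


@pytest.fixture(scope="session")
def ref_sim(small_config):
    return sim.simulate_reference_map(small_config)


@pytest.fixture(scope="session")
def atlas(small_config, ref_sim):
    """(CountMatrix, GroundTruth) for the small synthetic atlas."""
    return sim.simulate_cells(small_config, ref_sim)


@pytest.fixture(scope="session")
def preprocessed(atlas):
    matrix, _ = atlas
    return pp.preprocess(matrix, n_genes=150, n_pcs=10)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
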