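import numpy as np
import pytest

from tfnbs import GeneratorConfig, load_printed_params, simulate_nos_cohort
from tfnbs.atlas import EdgeIndex, ROIAtlas


@pytest.fixture(scope="session")
def printed_params():
    return load_printed_params()


@pytest.fixture(scope="session")
def published_cohort(printed_params):
    """Three-group cohort at the published sizes with the published edge effects."""
    edge_params, _ = printed_params
    return simulate_nos_cohort(edge_params, GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def small_null_cohort(printed_params):
    """Small cohort with no group effects anywhere (null edges only)."""
    edge_params, _ = printed_params
    null_means = {g: np.full_like(edge_params.means[g], 1.0e6) for g in edge_params.means}
    null_sds = {g: np.full_like(edge_params.sds[g], 0.25e6) for g in edge_params.sds}
    params = type(edge_params)(
        means=null_means,
        sds=null_sds,
        seeded_edges=np.array([], dtype=int),
        edge_index=edge_params.edge_index,
    )
    config = GeneratorConfig(
        n_per_group={"HC": 12, "PD": 12, "MSA": 12},
        gender_counts={"HC": (6, 6), "PD": (6, 6), "MSA": (6, 6)},
        seed=7,
    )
    return simulate_nos_cohort(params, config)


@pytest.fixture(scope="session")
def tiny_index():
    """5-node atlas (10 edges) for brute-force graph oracles."""
    return EdgeIndex(ROIAtlas(labels=tuple("ABCDE")))
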