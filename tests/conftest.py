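import numpy as np
import pytest

from genospecies.ani import AniConfig, ani_matrix, single_linkage_clusters
from genospecies.pipeline import FAST_NT_PARAMS
from genospecies.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default simulated cohort: 3 clusters of 5/4/4 plus 4 singletons."""
    return simulate_cohort(SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_cluster_cohort():
    """A faster 2-cluster cohort for alignment-heavy tests."""
    cfg = SimConfig(n_clusters=2, genomes_per_cluster=(3, 3), n_singleton_strains=1,
                    core_genes=25, cluster_accessory=5, private_genes_mean=3.0,
                    seed=7)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_ani(default_cohort):
    return ani_matrix(default_cohort.genomes, AniConfig(), FAST_NT_PARAMS)


@pytest.fixture(scope="session")
def default_assignment(default_ani):
    return single_linkage_clusters(default_ani, 94.0)


@pytest.fixture(scope="session")
def default_families(default_cohort):
    from genospecies.pangenome import build_graph, mcl

    graph = build_graph(default_cohort.proteins)
    return mcl(graph, inflation=1.5)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
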