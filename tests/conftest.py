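import networkx as nx
import pytest

from crosspath.synthgen import SynthConfig, SyntheticDataset, synthesize


@pytest.fixture
def triangle() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C"), ("C", "A")])
    return g


@pytest.fixture
def path_ab() -> nx.Graph:
    g = nx.Graph()
    g.add_edge("A", "B")
    return g


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    """Scaled-down study conditions for fast end-to-end tests."""
    return SynthConfig(
        n_genes=400,
        panel_sizes=(40, 30, 35),
        n_planted_common=6,
        n_pathways=40,
        pathway_size_range=(10, 30),
        n_enriched_pathways=4,
        module_size=4,
        n_samples_per_group=6,
        n_de_genes=20,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config) -> SyntheticDataset:
    return synthesize(small_config)
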