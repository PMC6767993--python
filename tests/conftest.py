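import sys
from pathlib import Path

import networkx as nx
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from htnet.network_build import InteractionNetwork
from htnet.synthetic_data import GeneratorConfig, generate_fixture, write_fixture


def make_network(edges, formula=(), disease=(), nodes=()):
    """Hand-built annotated network for worked examples."""
    g = nx.Graph()
    for n in nodes:
        g.add_node(n)
    for e in edges:
        a, b = e[:2]
        conf = e[2] if len(e) > 2 else 1.0
        g.add_edge(a, b, confidence=conf)
    for n in g.nodes():
        g.nodes[n]["is_formula_target"] = n in formula
        g.nodes[n]["is_disease_target"] = n in disease
    return InteractionNetwork(g)


SMALL_CONFIG = GeneratorConfig(
    seed=7,
    n_compounds=60,
    n_targets=8,
    n_disease_targets=30,
    n_background_nodes=88,
    n_planted_hubs=6,
    hub_degree_boost=40,
    n_pathways=12,
    planted_pathway_overlap=6,
    n_drugs=8,
    n_dmards=2,
)


@pytest.fixture(scope="session")
def small_bundle():
    """Reduced-scale fixture bundle used by most integration tests."""
    return generate_fixture(SMALL_CONFIG)


@pytest.fixture(scope="session")
def default_bundle():
    """The generator's default study conditions (full desk scale)."""
    return generate_fixture(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def small_fixture_dir(small_bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    paths = write_fixture(small_bundle, out)
    return paths
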