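"""The four topological indicators: worked examples with hand-derived
values, exact agreement with brute-force oracles on random graphs, and
structural invariants."""

import random

import networkx as nx
import pytest

from conftest import make_network
from htnet.network_build import InteractionNetwork
from htnet.topology import betweenness, closeness, core_numbers, degrees, profile
from oracles import (
    brute_betweenness,
    brute_closeness,
    brute_core_numbers,
    brute_degrees,
)


def path_abc():
    return make_network([("A", "B"), ("B", "C")])


# ---------------------------------------------------------------------------
# worked examples


def test_degrees_on_path_and_star():
    assert degrees(path_abc()) == {"A": 1, "B": 2, "C": 1}
    star = make_network([("H", leaf) for leaf in "ABCDE"])
    assert degrees(star)["H"] == 5
    assert degrees(make_network([])) == {}


def test_betweenness_path_center_is_one():
    # single pair (A, C); its only shortest path passes B; normalizer = 1
    btw = betweenness(path_abc())
    assert btw == {"A": 0.0, "B": 1.0, "C": 0.0}


def test_betweenness_cycle_symmetric():
    cycle = make_network([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])
    values = set(betweenness(cycle).values())
    assert len(values) == 1


def test_betweenness_complete_graph_zero():
    k5 = InteractionNetwork(nx.complete_graph(5))
    assert all(v == 0.0 for v in betweenness(k5).values())


def test_closeness_path_and_complete():
    clo = closeness(path_abc())
    assert clo["B"] == pytest.approx(1.0)
    assert clo["A"] == pytest.approx(2 / 3)
    k4 = InteractionNetwork(nx.complete_graph(4))
    assert all(v == pytest.approx(1.0) for v in closeness(k4).values())


def test_closeness_disconnected_reachability_weighted():
    # two disjoint edges on 4 nodes: r=1, S=1, n=4 -> (1/1)*(1/3)
    net = make_network([("A", "B"), ("C", "D")])
    assert all(v == pytest.approx(1 / 3) for v in closeness(net).values())


def test_core_numbers_triangle_with_pendant():
    net = make_network([("A", "B"), ("B", "C"), ("C", "A"), ("C", "P")])
    assert core_numbers(net) == {"A": 2, "B": 2, "C": 2, "P": 1}


def test_core_numbers_edge_and_clique():
    assert core_numbers(make_network([("A", "B")])) == {"A": 1, "B": 1}
    k6 = InteractionNetwork(nx.complete_graph(6))
    assert set(core_numbers(k6).values()) == {5}


def test_profile_bundles_all_four_metrics():
    profiles = {p.node: p for p in profile(path_abc())}
    b = profiles["B"]
    assert (b.degree, b.betweenness, b.closeness, b.kcore) == (2, 1.0, 1.0, 1)
    triangle = make_network([("A", "B"), ("B", "C"), ("C", "A")])
    for p in profile(triangle):
        assert (p.degree, p.betweenness, p.closeness, p.kcore) == (2, 0.0, 1.0, 2)
    assert profile(make_network([])) == []


# ---------------------------------------------------------------------------
# oracle equivalence and invariants


def random_graphs(n_graphs=200, max_nodes=12, seed=0):
    rng = random.Random(seed)
    for _ in range(n_graphs):
        n = rng.randint(2, max_nodes)
        p = rng.uniform(0.1, 0.7)
        nodes = [f"N{i}" for i in range(n)]
        edges = [
            (a, b)
            for i, a in enumerate(nodes)
            for b in nodes[i + 1:]
            if rng.random() < p
        ]
        yield nodes, edges


def test_all_metrics_match_bruteforce_on_random_graphs():
    """Exact agreement with explicit path enumeration and exhaustive peeling
    on 200 random graphs of up to 12 nodes."""
    for nodes, edges in random_graphs():
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        net = InteractionNetwork(g)
        assert degrees(net) == brute_degrees(nodes, edges)
        assert core_numbers(net) == brute_core_numbers(nodes, edges)
        expected_btw = brute_betweenness(nodes, edges)
        got_btw = betweenness(net)
        for n in nodes:
            assert got_btw[n] == pytest.approx(expected_btw[n], abs=1e-12)
        expected_clo = brute_closeness(nodes, edges)
        got_clo = closeness(net)
        for n in nodes:
            assert got_clo[n] == pytest.approx(expected_clo[n], abs=1e-12)


def test_metrics_invariant_under_relabeling():
    rng = random.Random(5)
    for nodes, edges in random_graphs(n_graphs=20, seed=5):
        mapping = dict(zip(nodes, rng.sample(nodes, len(nodes))))
        g1 = nx.Graph()
        g1.add_nodes_from(nodes)
        g1.add_edges_from(edges)
        g2 = nx.relabel_nodes(g1, mapping, copy=True)
        p1 = {p.node: p for p in profile(InteractionNetwork(g1))}
        p2 = {p.node: p for p in profile(InteractionNetwork(g2))}
        for n in nodes:
            a, b = p1[n], p2[mapping[n]]
            assert (a.degree, a.kcore) == (b.degree, b.kcore)
            assert a.betweenness == pytest.approx(b.betweenness)
            assert a.closeness == pytest.approx(b.closeness)


def test_adding_edge_never_decreases_degree_or_core():
    rng = random.Random(11)
    for nodes, edges in random_graphs(n_graphs=30, seed=11):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        non_edges = list(nx.non_edges(g))
        if not non_edges:
            continue
        deg0, core0 = degrees(g), core_numbers(g)
        g.add_edge(*rng.choice(non_edges))
        deg1, core1 = degrees(g), core_numbers(g)
        assert all(deg1[n] >= deg0[n] for n in nodes)
        assert all(core1[n] >= core0[n] for n in nodes)


def test_betweenness_unnormalized_variant_scales():
    net = path_abc()
    raw = betweenness(net, normalized=False)
    assert raw["B"] == pytest.approx(1.0)  # (n-1)(n-2)/2 = 1 for n=3
    square_plus = make_network(
        [("A", "B"), ("B", "C"), ("C", "D"), ("D", "A"), ("D", "E")]
    )
    norm = betweenness(square_plus, normalized=True)
    unnorm = betweenness(square_plus, normalized=False)
    scale = (5 - 1) * (5 - 2) / 2
    for n in norm:
        assert unnorm[n] == pytest.approx(norm[n] * scale)
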