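"""Two-stage hub screen: the strict 2x-median-degree rule, the
four-indicator major-hub rule on the hub subnetwork, and their invariants."""

import networkx as nx
import pytest

from conftest import make_network
from htnet.errors import ValidationError
from htnet.hub_screening import find_hubs, find_major_hubs, screen
from htnet.network_build import InteractionNetwork


def star(n_leaves=5):
    return make_network([("H", f"L{i}") for i in range(n_leaves)], formula={"H"})


def test_star_center_is_sole_hub():
    # degrees (5,1,1,1,1,1): median 1, threshold 2, only the center exceeds it
    hubs, thresholds = find_hubs(star(), 2.0)
    assert hubs == {"H"}
    assert thresholds.degree_median_full == 1
    assert thresholds.hub_degree_threshold == 2


def test_path_has_no_hubs():
    path = make_network([("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")])
    hubs, thresholds = find_hubs(path, 2.0)
    # degrees (1,2,2,2,1): median 2, threshold 4, max degree 2
    assert hubs == set()
    assert thresholds.hub_degree_threshold == 4


def test_even_count_median_is_mean_of_central_pair():
    # star-5 plus one leaf-leaf edge: degrees (5,2,2,1,1,1) ->
    # median (1+2)/2 = 1.5, threshold 3, hub = center only
    net = make_network(
        [("H", leaf) for leaf in "ABCDE"] + [("A", "B")]
    )
    hubs, thresholds = find_hubs(net, 2.0)
    assert thresholds.degree_median_full == 1.5
    assert thresholds.hub_degree_threshold == 3.0
    assert hubs == {"H"}


def test_hub_rule_is_strict():
    # center degree exactly 2x median is NOT a hub
    net = make_network([("H", "A"), ("H", "B")])  # degrees (2,1,1): median 1
    hubs, _ = find_hubs(net, 2.0)
    assert hubs == set()


def test_empty_network_rejected():
    with pytest.raises(ValidationError):
        find_hubs(InteractionNetwork(nx.Graph()), 2.0)
    with pytest.raises(ValidationError):
        find_hubs(star(), 0.0)


def test_hub_monotonicity_in_multiplier():
    net = make_network(
        [(f"N{i}", f"N{j}") for i in range(8) for j in range(i + 1, 8) if (i * j) % 3]
    )
    previous = None
    for multiplier in (0.5, 1.0, 1.5, 2.0, 3.0):
        hubs, _ = find_hubs(net, multiplier)
        if previous is not None:
            assert hubs <= previous
        previous = hubs


def test_tiny_multiplier_degenerate_limit():
    hubs, _ = find_hubs(star(), 0.0001)
    assert hubs == {"H", "L0", "L1", "L2", "L3", "L4"}
    result = screen(star(), 0.0001)
    assert result.major_hubs <= result.hubs


# ---------------------------------------------------------------------------
# major hubs


def test_identical_hubs_tie_on_all_medians_yields_none():
    k4 = InteractionNetwork(nx.complete_graph(["A", "B", "C", "D"]))
    for n in k4.graph.nodes:
        k4.graph.nodes[n].update(is_formula_target=True, is_disease_target=False)
    result = find_major_hubs(k4, {"A", "B", "C", "D"})
    assert result.major_hubs == set()


def test_two_tier_hub_set_selects_upper_tier():
    """Clique-plus-pendant hub graph: tier A (clique members) strictly beats
    tier B (pendants) on degree, betweenness, closeness and k-core, so the
    four-median conjunction selects exactly tier A."""
    edges = [("A1", "A2"), ("A1", "A3"), ("A2", "A3"),
             ("B1", "A1"), ("B2", "A2"), ("B3", "A3")]
    net = make_network(edges, formula={"A1", "A2", "B1"})
    hubs = {"A1", "A2", "A3", "B1", "B2", "B3"}
    result = find_major_hubs(net, hubs)
    # hand enumeration: degrees A=3/B=1 (median 2); kcore A=2/B=1 (median 1.5);
    # betweenness A>0/B=0; closeness A>B; medians sit between the tiers
    assert result.major_hubs == {"A1", "A2", "A3"}
    assert result.formula_major_hubs == {"A1", "A2"}
    assert result.thresholds.indicator_medians["degree"] == 2.0
    assert result.thresholds.indicator_medians["kcore"] == 1.5


def test_node_tied_on_one_indicator_is_excluded():
    # B1 gains an extra edge to A1: still below the degree median but now
    # every candidate must beat all four medians simultaneously
    edges = [("A1", "A2"), ("A1", "A3"), ("A2", "A3"),
             ("B1", "A1"), ("B1", "A2"), ("B2", "A2"), ("B3", "A3")]
    net = make_network(edges)
    hubs = {"A1", "A2", "A3", "B1", "B2", "B3"}
    result = find_major_hubs(net, hubs)
    for node in result.major_hubs:
        p = next(q for q in result.hub_profiles if q.node == node)
        medians = result.thresholds.indicator_medians
        assert p.degree > medians["degree"]
        assert p.betweenness > medians["betweenness"]
        assert p.closeness > medians["closeness"]
        assert p.kcore > medians["kcore"]
    assert "B1" not in result.major_hubs  # kcore ties the median of 2


def test_empty_hub_set_rejected():
    with pytest.raises(ValidationError):
        find_major_hubs(star(), set())
    with pytest.raises(ValidationError):
        find_major_hubs(star(), {"NOT_A_NODE"})


def test_major_hub_bound_half_of_hubs():
    # strict medians: at most ceil(|hubs|/2) exceed any single indicator
    net = make_network(
        [(f"N{i}", f"N{j}") for i in range(10) for j in range(i + 1, 10) if (i + j) % 3]
    )
    result = screen(net, 0.5)
    assert len(result.major_hubs) <= -(-len(result.hubs) // 2)


def test_screen_composes_and_is_deterministic():
    net = make_network(
        [("H", f"L{i}") for i in range(6)] + [("L0", "L1"), ("L2", "L3")],
        formula={"H", "L0"},
    )
    r1 = screen(net, 2.0)
    r2 = screen(net, 2.0)
    assert r1.hubs == r2.hubs
    assert r1.major_hubs == r2.major_hubs
    assert r1.thresholds.indicator_medians == r2.thresholds.indicator_medians
    assert r1.major_hubs <= r1.hubs
    assert r1.formula_major_hubs <= r1.major_hubs


def test_metrics_scope_full_network_variant():
    edges = [("A1", "A2"), ("A1", "A3"), ("A2", "A3"),
             ("B1", "A1"), ("B2", "A2"), ("B3", "A3"),
             ("B1", "X1"), ("X1", "X2")]
    net = make_network(edges)
    hubs = {"A1", "A2", "A3", "B1", "B2", "B3"}
    sub = find_major_hubs(net, hubs, metrics_scope="hub-subnet")
    full = find_major_hubs(net, hubs, metrics_scope="full")
    # scoring on the full graph counts X-edges; both remain valid screens
    assert sub.major_hubs <= hubs and full.major_hubs <= hubs
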