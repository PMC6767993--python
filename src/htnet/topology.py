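"""The four per-node topological indicators used for hub screening.

All metrics are computed on the unweighted simple graph (edge confidences
are ignored once the network is built):

* degree — incident edge count;
* betweenness — shortest-path betweenness with endpoints excluded,
  fractional counting over equal-length paths, normalized by
  (n-1)(n-2)/2 for n >= 3 (an unnormalized variant is available since the
  indicator's scale convention differs between tools);
* closeness — reachability-weighted: a node v with r reachable others at
  total distance S scores (r/S) * (r/(n-1)), which reduces to (n-1)/S on a
  connected graph and to 0 for an isolated node, so disconnected networks
  yield finite comparable values;
* k-core index — the largest k such that the node survives iterative
  minimum-degree peeling to the k-core.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx


@dataclass(frozen=True)
class TopologyProfile:
    """Bundle of the four indicators for one node."""

    node: str
    degree: int
    betweenness: float
    closeness: float
    kcore: int


def _as_graph(network) -> nx.Graph:
    if isinstance(network, nx.Graph):
        return network
    return network.graph


def degrees(network) -> dict[str, int]:
    g = _as_graph(network)
    return {n: d for n, d in g.degree()}


def betweenness(network, normalized: bool = True) -> dict[str, float]:
    g = _as_graph(network)
    return nx.betweenness_centrality(g, normalized=normalized)


def closeness(network) -> dict[str, float]:
    g = _as_graph(network)
    return nx.closeness_centrality(g, wf_improved=True)


def core_numbers(network) -> dict[str, int]:
    g = _as_graph(network)
    return nx.core_number(g)


def profile(network, betweenness_normalized: bool = True) -> list[TopologyProfile]:
    """One :class:`TopologyProfile` per node, in sorted node order."""
    g = _as_graph(network)
    deg = degrees(g)
    btw = betweenness(g, normalized=betweenness_normalized)
    clo = closeness(g)
    core = core_numbers(g)
    return [
        TopologyProfile(n, deg[n], btw[n], clo[n], core[n]) for n in sorted(g.nodes())
    ]
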