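"""Construction of the annotated formula-disease interaction network.

The network is an undirected simple graph whose nodes are proteins that are
formula targets, disease targets, or both (tracked as boolean node flags),
and whose edges carry a STRING-style combined confidence in [0, 1]. Only
edges meeting the confidence cut with both endpoints in the allowed target
universe are admitted, and only proteins with at least one surviving edge
become nodes — isolated proteins cannot participate in topology-driven hub
screening (a ``keep_isolated`` switch retains them for sensitivity checks).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .errors import ValidationError
from .io_formats import PPIEdgeRecord, canonical_symbol

log = logging.getLogger(__name__)

# STRING's published "medium confidence" cut on the combined score.
MEDIUM_CONFIDENCE = 0.400


@dataclass
class InteractionNetwork:
    """Undirected simple graph of annotated proteins with weighted edges.

    Thin wrapper over :class:`networkx.Graph`; node attributes are
    ``is_formula_target`` / ``is_disease_target`` and the edge attribute is
    ``confidence``.
    """

    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> set[str]:
        return set(self.graph.nodes())

    def formula_targets(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("is_formula_target")}

    def disease_targets(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("is_disease_target")}

    def edge_set(self) -> set[tuple[str, str, float]]:
        return {
            (min(a, b), max(a, b), d["confidence"])
            for a, b, d in self.graph.edges(data=True)
        }

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        if self.nodes() != other.nodes() or self.edge_set() != other.edge_set():
            return False
        return all(
            self.graph.nodes[n] == other.graph.nodes[n] for n in self.graph.nodes()
        )


def build_network(
    edges: Iterable[PPIEdgeRecord],
    formula_targets: set[str],
    disease_targets: set[str],
    min_confidence: float = MEDIUM_CONFIDENCE,
    keep_isolated: bool = False,
) -> InteractionNetwork:
    """Assemble the formula-disease PPI network from a filtered edge list.

    An edge survives iff its confidence is >= ``min_confidence`` and both
    endpoints belong to ``formula_targets | disease_targets``. Node flags
    record membership in each target set. With ``keep_isolated`` the allowed
    proteins without any surviving edge are added as degree-0 nodes.
    """
    if not (0.0 <= min_confidence <= 1.0):
        raise ValidationError(f"min_confidence {min_confidence} outside [0, 1]")
    formula = {canonical_symbol(t) for t in formula_targets}
    disease = {canonical_symbol(t) for t in disease_targets}
    allowed = formula | disease
    graph = nx.Graph()

    def _add_node(p: str) -> None:
        graph.add_node(
            p, is_formula_target=p in formula, is_disease_target=p in disease
        )

    n_dropped_conf = 0
    n_dropped_membership = 0
    for e in edges:
        if e.confidence < min_confidence:
            n_dropped_conf += 1
            continue
        if e.protein_a not in allowed or e.protein_b not in allowed:
            n_dropped_membership += 1
            continue
        _add_node(e.protein_a)
        _add_node(e.protein_b)
        graph.add_edge(e.protein_a, e.protein_b, confidence=e.confidence)
    if keep_isolated:
        for p in sorted(allowed - set(graph.nodes())):
            _add_node(p)
    log.info(
        "build_network: kept %d edges / %d nodes (dropped %d below confidence, %d outside target sets)",
        graph.number_of_edges(), graph.number_of_nodes(),
        n_dropped_conf, n_dropped_membership,
    )
    return InteractionNetwork(graph)


def induced_subnetwork(network: InteractionNetwork, keep: set[str]) -> InteractionNetwork:
    """Subgraph induced on ``keep``; ids absent from the network are ignored
    (with a logged count), confidences and flags preserved."""
    present = network.nodes()
    keep_canonical = {canonical_symbol(k) for k in keep}
    extras = keep_canonical - present
    if extras:
        log.info("induced_subnetwork: ignoring %d ids absent from network", len(extras))
    sub = network.graph.subgraph(keep_canonical & present).copy()
    return InteractionNetwork(sub)
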