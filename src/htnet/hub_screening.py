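"""Two-stage topological hub screen.

Stage 1 (hubs): a node is a hub iff its degree strictly exceeds
``multiplier`` x the median degree of all nodes in the network (default
multiplier 2). Medians over an even count are the arithmetic mean of the
two central order statistics.

Stage 2 (major hubs): the four indicators (degree, betweenness, closeness,
k-core index) are recomputed on the hub-induced subnetwork, their medians
taken over the hub set, and a hub is a major hub iff it is strictly greater
than ALL four medians simultaneously. Strictness makes the all-tied case
well defined (no major hubs) and bounds the survivors by half the hub set
per indicator. A ``metrics_scope`` switch allows scoring hubs on the full
network instead of the hub subnetwork.

The screen is a pure function of the network: no randomness, no tie-break
order dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median

from .errors import ValidationError
from .network_build import InteractionNetwork, induced_subnetwork
from .topology import TopologyProfile, profile

INDICATORS = ("degree", "betweenness", "closeness", "kcore")


@dataclass
class ThresholdSet:
    """The medians and cutoffs the screen actually used."""

    degree_median_full: float
    multiplier: float
    hub_degree_threshold: float
    indicator_medians: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.hub_degree_threshold == self.multiplier * self.degree_median_full


@dataclass
class ScreenResult:
    hubs: set[str]
    major_hubs: set[str]
    formula_major_hubs: set[str]
    thresholds: ThresholdSet
    hub_profiles: list[TopologyProfile] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "hubs": sorted(self.hubs),
            "major_hubs": sorted(self.major_hubs),
            "formula_major_hubs": sorted(self.formula_major_hubs),
            "thresholds": {
                "degree_median_full": self.thresholds.degree_median_full,
                "multiplier": self.thresholds.multiplier,
                "hub_degree_threshold": self.thresholds.hub_degree_threshold,
                "indicator_medians": dict(self.thresholds.indicator_medians),
            },
            "hub_profiles": [
                {
                    "node": p.node,
                    "degree": p.degree,
                    "betweenness": p.betweenness,
                    "closeness": p.closeness,
                    "kcore": p.kcore,
                }
                for p in self.hub_profiles
            ],
        }


def find_hubs(
    network: InteractionNetwork, multiplier: float = 2.0
) -> tuple[set[str], ThresholdSet]:
    """Stage 1: nodes with degree strictly above multiplier x median degree."""
    if network.n_nodes == 0:
        raise ValidationError("cannot screen an empty network")
    if multiplier <= 0:
        raise ValidationError(f"multiplier must be positive, got {multiplier}")
    deg = dict(network.graph.degree())
    med = float(median(deg.values()))
    threshold = multiplier * med
    hubs = {n for n, d in deg.items() if d > threshold}
    return hubs, ThresholdSet(med, multiplier, threshold)


def find_major_hubs(
    network: InteractionNetwork,
    hubs: set[str],
    thresholds: ThresholdSet | None = None,
    metrics_scope: str = "hub-subnet",
    betweenness_normalized: bool = True,
) -> ScreenResult:
    """Stage 2: hubs strictly above the hub-set median of all four indicators."""
    if not hubs:
        raise ValidationError("hub set is empty")
    missing = hubs - network.nodes()
    if missing:
        raise ValidationError(f"hubs not in network: {sorted(missing)[:5]}")
    if metrics_scope == "hub-subnet":
        scored = induced_subnetwork(network, hubs)
    elif metrics_scope == "full":
        scored = network
    else:
        raise ValidationError(f"unknown metrics_scope {metrics_scope!r}")
    profiles = [p for p in profile(scored, betweenness_normalized) if p.node in hubs]
    medians = {
        ind: float(median(getattr(p, ind) for p in profiles)) for ind in INDICATORS
    }
    major = {
        p.node
        for p in profiles
        if all(getattr(p, ind) > medians[ind] for ind in INDICATORS)
    }
    formula = network.formula_targets()
    if thresholds is None:
        thresholds = ThresholdSet(0.0, 1.0, 0.0)
    thresholds.indicator_medians = medians
    return ScreenResult(
        hubs=set(hubs),
        major_hubs=major,
        formula_major_hubs=major & formula,
        thresholds=thresholds,
        hub_profiles=profiles,
    )


def screen(
    network: InteractionNetwork,
    multiplier: float = 2.0,
    metrics_scope: str = "hub-subnet",
    betweenness_normalized: bool = True,
) -> ScreenResult:
    """Run both stages; deterministic for a given network."""
    hubs, thresholds = find_hubs(network, multiplier)
    if not hubs:
        return ScreenResult(set(), set(), set(), thresholds, [])
    return find_major_hubs(
        network, hubs, thresholds, metrics_scope, betweenness_normalized
    )
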