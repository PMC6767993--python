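"""Deterministic synthetic fixtures with planted, verified structure.

The generator emulates the statistical shape of a multi-herb
network-pharmacology study so the whole pipeline runs with no database
access: a compound table spread over ten herbs, reference ligand sets with
designated active compounds (the intended predictions), curated
compound-target links covering the remaining formula targets, a disease
target list that partially overlaps the formula targets, an approved-drug
table with shared targets, a STRING-dialect PPI edge list whose degree
distribution is Erdos-Renyi background plus planted high-degree hubs, and
a GMT collection with one pathway planted to contain the hubs.

Planting is verified, not merely attempted: before returning, the generator
runs the hub rule on its own output and trims or boosts edges until the
planted hub set is recovered exactly, and re-randomizes any compound whose
fingerprint accidentally crosses the similarity threshold for an unintended
target. A bounded number of repair rounds is attempted, then a
ValidationError is raised. A single integer seed drives all randomness
through one explicitly threaded NumPy generator; equal seeds give
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .errors import ValidationError
from .hub_screening import find_hubs, screen
from .io_formats import (
    CompoundRecord,
    DrugRecord,
    PathwayGeneSet,
    PPIEdgeRecord,
    TargetLigandSet,
    format_fingerprint,
    write_gene_sets_gmt,
)
from .network_build import InteractionNetwork, build_network
from .target_prediction import DEFAULT_TC_THRESHOLD, predict_targets

HERBS = [f"herb{i:02d}" for i in range(1, 11)]


@dataclass
class GeneratorConfig:
    """Knobs of the fixture generator.

    Defaults mirror the order of magnitude of a ten-herb formula study at
    desk scale: 800 compounds, a 300-protein interaction layer with 12
    planted hubs, 100 disease targets of which 12% are also formula
    targets, 23 approved drugs and 30 pathways.
    """

    seed: int = 0
    n_compounds: int = 800
    fingerprint_length: int = 64
    fingerprint_density: float = 0.3
    n_targets: int = 40  # targets with reference ligand sets (predictable)
    ligands_per_target: int = 4
    n_disease_targets: int = 100
    overlap_fraction: float = 0.12
    n_background_nodes: int = 288
    n_planted_hubs: int = 12
    hub_degree_boost: int = 80
    edge_prob_background: float = 0.04
    confidence_range: tuple[float, float] = (0.4, 1.0)
    n_pathways: int = 30
    planted_pathway_overlap: int = 12
    n_drugs: int = 23
    n_dmards: int = 4
    tc_threshold: float = DEFAULT_TC_THRESHOLD
    hub_multiplier: float = 2.0
    max_repair_rounds: int = 60

    def validate(self) -> None:
        total = self.n_background_nodes + self.n_planted_hubs
        if self.fingerprint_length < 16:
            raise ValidationError("fingerprint_length must be >= 16")
        for name in (
            "n_compounds", "n_targets", "ligands_per_target", "n_disease_targets",
            "n_background_nodes", "n_planted_hubs", "n_pathways", "n_drugs",
        ):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValidationError("overlap_fraction outside [0, 1]")
        if not (0.0 < self.edge_prob_background < 1.0):
            raise ValidationError("edge_prob_background outside (0, 1)")
        lo, hi = self.confidence_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValidationError("confidence_range must be ordered within [0, 1]")
        if self.hub_degree_boost > self.n_background_nodes:
            raise ValidationError(
                f"hub_degree_boost {self.hub_degree_boost} exceeds available "
                f"background partners ({self.n_background_nodes})"
            )
        if self.planted_pathway_overlap > self.n_planted_hubs:
            raise ValidationError(
                "planted_pathway_overlap cannot exceed n_planted_hubs"
            )
        if self.n_disease_targets >= total:
            raise ValidationError("n_disease_targets must leave formula-only nodes")
        if self.n_dmards > self.n_drugs:
            raise ValidationError("n_dmards cannot exceed n_drugs")


@dataclass
class GroundTruth:
    """Machine-readable record of everything the generator planted."""

    planted_hubs: list[str]
    intended_cti: list[tuple[str, str]]  # (compound_id, target_id) predicted pairs
    planted_pathway_id: str
    formula_targets: list[str]
    disease_targets: list[str]
    overlap_targets: list[str]

    def to_dict(self) -> dict:
        return {
            "planted_hubs": self.planted_hubs,
            "intended_cti": [list(p) for p in self.intended_cti],
            "planted_pathway_id": self.planted_pathway_id,
            "formula_targets": self.formula_targets,
            "disease_targets": self.disease_targets,
            "overlap_targets": self.overlap_targets,
        }

    @staticmethod
    def from_dict(d: dict) -> "GroundTruth":
        return GroundTruth(
            planted_hubs=list(d["planted_hubs"]),
            intended_cti=[tuple(p) for p in d["intended_cti"]],
            planted_pathway_id=d["planted_pathway_id"],
            formula_targets=list(d["formula_targets"]),
            disease_targets=list(d["disease_targets"]),
            overlap_targets=list(d["overlap_targets"]),
        )


@dataclass
class FixtureBundle:
    config: GeneratorConfig
    compounds: list[CompoundRecord]
    ligand_sets: list[TargetLigandSet]
    known_cti: list[tuple[str, str]]  # (compound_id, target_id)
    disease_targets: set[str]
    drugs: list[DrugRecord]
    ppi_edges: list[PPIEdgeRecord]
    gene_sets: list[PathwayGeneSet]
    ground_truth: GroundTruth


def _random_fingerprint(rng: np.random.Generator, cfg: GeneratorConfig) -> np.ndarray:
    return (rng.random(cfg.fingerprint_length) < cfg.fingerprint_density).astype(np.uint8)


def _plant_graph(rng: np.random.Generator, cfg: GeneratorConfig, nodes: list[str],
                 planted: list[str]) -> nx.Graph:
    """ER background plus two-tier hub wiring; every node left with degree >= 1.

    All planted hubs are boosted far above the 2x-median degree rule by
    wiring them to random background partners. Among themselves the hubs are
    wired deterministically into two tiers — a core clique (first half) with
    the remaining hubs attached as single pendants in round-robin — so the
    hub-induced subgraph separates cleanly on all four indicators and the
    strict major-hub rule has a nonempty, proper solution.
    """
    total = len(nodes)
    planted_set = set(planted)
    background = [n for n in nodes if n not in planted_set]
    g: nx.Graph = nx.Graph()
    g.add_nodes_from(nodes)
    # upper-triangle Bernoulli draw for the background layer
    idx = np.triu_indices(total, k=1)
    mask = rng.random(idx[0].size) < cfg.edge_prob_background
    for i, j in zip(idx[0][mask], idx[1][mask]):
        a, b = nodes[i], nodes[j]
        if a in planted_set and b in planted_set:
            continue  # hub-hub wiring is deterministic, below
        g.add_edge(a, b)
    # tier A: core clique; tier B: one pendant edge each, round-robin
    n_core = max(2, int(np.ceil(len(planted) / 2)))
    core, periphery = planted[:n_core], planted[n_core:]
    for i in range(len(core)):
        for j in range(i + 1, len(core)):
            g.add_edge(core[i], core[j])
    for i, hub in enumerate(periphery):
        g.add_edge(hub, core[i % len(core)])
    # degree boost towards random background partners
    for hub in planted:
        partners = rng.choice(len(background), size=cfg.hub_degree_boost, replace=False)
        for p in partners:
            g.add_edge(hub, background[p])
    for node in list(nx.isolates(g)):
        partner = background[int(rng.integers(len(background)))]
        while partner == node:
            partner = background[int(rng.integers(len(background)))]
        g.add_edge(node, partner)
    return g


def _repair_hubs(rng: np.random.Generator, cfg: GeneratorConfig, g: nx.Graph,
                 planted: list[str], formula: set[str], disease: set[str]) -> nx.Graph:
    """Trim or boost edges until the hub rule recovers exactly the planted set
    and the major-hub stage is nondegenerate (0 < major < hubs, with at least
    one formula-flagged major hub)."""
    planted_set = set(planted)
    nodes = sorted(g.nodes())
    for _ in range(cfg.max_repair_rounds):
        net = InteractionNetwork(_flagged(g, formula, disease))
        hubs, thresholds = find_hubs(net, cfg.hub_multiplier)
        extras = hubs - planted_set
        missing = planted_set - hubs
        if not extras and not missing:
            result = screen(net, cfg.hub_multiplier)
            if (
                result.major_hubs
                and result.major_hubs < result.hubs
                and result.formula_major_hubs
            ):
                return g
            raise ValidationError(
                "planted hub tiers did not separate under the four-indicator "
                "rule; config is infeasible"
            )
        threshold = thresholds.hub_degree_threshold
        for node in extras:
            # drop background edges (never hub-incident ones) until compliant
            removable = [
                (node, nb) for nb in list(g.neighbors(node))
                if nb not in planted_set and g.degree(nb) > 1
            ]
            rng.shuffle(removable)
            while g.degree(node) > threshold and removable:
                g.remove_edge(*removable.pop())
        for node in missing:
            candidates = [
                n for n in nodes
                if n != node and n not in planted_set and not g.has_edge(node, n)
            ]
            rng.shuffle(candidates)
            while g.degree(node) <= threshold and candidates:
                g.add_edge(node, candidates.pop())
    raise ValidationError(
        "could not plant the hub structure within the repair budget; "
        "config is infeasible"
    )


def _flagged(g: nx.Graph, formula: set[str], disease: set[str]) -> nx.Graph:
    out = nx.Graph()
    for n in g.nodes():
        out.add_node(n, is_formula_target=n in formula, is_disease_target=n in disease)
    out.add_edges_from(g.edges())
    return out


def generate_fixture(config: GeneratorConfig | None = None) -> FixtureBundle:
    """Generate a complete, internally consistent fixture bundle.

    Deterministic for a fixed config; all planted guarantees are re-verified
    before returning.
    """
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    total = cfg.n_background_nodes + cfg.n_planted_hubs
    nodes = [f"G{i:04d}" for i in range(total)]

    # --- membership layers -------------------------------------------------
    disease_idx = rng.choice(total, size=cfg.n_disease_targets, replace=False)
    disease = {nodes[i] for i in disease_idx}
    n_overlap = int(round(cfg.overlap_fraction * cfg.n_disease_targets))
    overlap = set(rng.choice(sorted(disease), size=n_overlap, replace=False)) if n_overlap else set()
    formula = (set(nodes) - disease) | overlap

    # --- planted hubs: mostly formula targets, some disease-only ----------
    n_formula_hubs = max(1, int(np.ceil(0.7 * cfg.n_planted_hubs)))
    n_formula_hubs = min(n_formula_hubs, cfg.n_planted_hubs)
    formula_pool = sorted(formula)
    disease_only_pool = sorted(disease - formula)
    planted = list(rng.choice(formula_pool, size=n_formula_hubs, replace=False))
    n_rest = cfg.n_planted_hubs - n_formula_hubs
    if n_rest:
        pool = disease_only_pool if len(disease_only_pool) >= n_rest else formula_pool
        rest = [p for p in rng.choice(pool, size=len(pool), replace=False)
                if p not in planted][:n_rest]
        planted.extend(rest)
    if len(planted) < cfg.n_planted_hubs:
        raise ValidationError("could not place all planted hubs")
    planted = [str(p) for p in planted]  # formula-target hubs first: they form the core tier

    # --- interaction layer -------------------------------------------------
    g = _plant_graph(rng, cfg, nodes, planted)
    g = _repair_hubs(rng, cfg, g, planted, formula, disease)
    conf_lo, conf_hi = cfg.confidence_range
    ppi_edges = []
    for a, b in sorted(g.edges()):
        a, b = (a, b) if a <= b else (b, a)
        conf = float(conf_lo + (conf_hi - conf_lo) * rng.random())
        ppi_edges.append(PPIEdgeRecord(a, b, round(conf, 3)))

    # --- compounds and ligand sets -----------------------------------------
    compounds = [
        CompoundRecord(
            compound_id=f"C{i:04d}",
            name=f"compound-{i}",
            herb=HERBS[int(rng.integers(len(HERBS)))],
            fingerprint=_random_fingerprint(rng, cfg),
        )
        for i in range(cfg.n_compounds)
    ]
    ligand_target_ids = sorted(
        rng.choice(formula_pool, size=min(cfg.n_targets, len(formula_pool)), replace=False)
    )
    ligand_sets = [
        TargetLigandSet(
            tid, [_random_fingerprint(rng, cfg) for _ in range(cfg.ligands_per_target)]
        )
        for tid in ligand_target_ids
    ]
    # designate active compounds: copy a ligand fingerprint with light
    # mutation that provably stays above the similarity threshold
    intended: list[tuple[str, str]] = []
    free_compounds = list(rng.permutation(cfg.n_compounds))
    for ls in ligand_sets:
        n_active = int(rng.integers(1, 4))
        for _ in range(n_active):
            if not free_compounds:
                break
            ci = free_compounds.pop()
            template = ls.ligands[int(rng.integers(len(ls.ligands)))].copy()
            fp = template.copy()
            flips = rng.choice(cfg.fingerprint_length, size=2, replace=False)
            fp[flips] ^= 1
            inter = int(np.logical_and(fp, template).sum())
            union = int(np.logical_or(fp, template).sum())
            if union == 0 or inter / union < cfg.tc_threshold:
                fp = template.copy()  # fall back to an exact copy (Tc = 1)
            compounds[ci] = dataclasses.replace(compounds[ci], fingerprint=fp)
            intended.append((compounds[ci].compound_id, ls.target_id))
    intended = sorted(set(intended))

    # --- verify predictions: no accidental pairs above threshold -----------
    intended_set = set(intended)
    for _ in range(cfg.max_repair_rounds):
        predicted = {
            (r.compound_id, r.target_id)
            for r in predict_targets(compounds, ligand_sets, cfg.tc_threshold)
        }
        accidental = predicted - intended_set
        if not accidental:
            break
        by_id = {c.compound_id: i for i, c in enumerate(compounds)}
        for cid, _tid in accidental:
            i = by_id[cid]
            if any(cid == c for c, _ in intended_set):
                continue  # never perturb a designated active
            compounds[i] = dataclasses.replace(
                compounds[i], fingerprint=_random_fingerprint(rng, cfg)
            )
    else:
        raise ValidationError("could not eliminate accidental predictions")
    if intended_set - predicted:
        raise ValidationError("intended predictions not recovered by the similarity rule")

    # --- curated CTIs cover the formula targets without ligand sets --------
    known: list[tuple[str, str]] = []
    predictable = set(ligand_target_ids)
    for tid in sorted(formula - predictable):
        k = int(rng.integers(1, 4))
        picks = rng.choice(cfg.n_compounds, size=k, replace=False)
        for ci in picks:
            known.append((compounds[int(ci)].compound_id, tid))
    known = sorted(set(known))

    # --- approved drugs -----------------------------------------------------
    drugs: list[DrugRecord] = []
    disease_only = sorted(disease - formula)
    for i in range(cfg.n_drugs):
        cls = "DMARD" if i < cfg.n_dmards else "NSAID"
        size = int(rng.integers(2, 16))
        if i >= cfg.n_drugs - 2 and disease_only:
            # a couple of drugs share nothing with the formula
            pool = disease_only
        else:
            pool = formula_pool
        size = min(size, len(pool))
        targets = frozenset(rng.choice(pool, size=size, replace=False))
        drugs.append(DrugRecord(f"D{i:03d}", f"drug-{i}", cls, targets))

    # --- pathways: one planted around the hubs ------------------------------
    gene_sets: list[PathwayGeneSet] = []
    planted_genes = set(rng.choice(planted, size=cfg.planted_pathway_overlap, replace=False))
    pad = rng.choice([n for n in nodes if n not in planted_genes], size=8, replace=False)
    planted_genes |= set(pad)
    gene_sets.append(PathwayGeneSet("PW0000", "planted pathway", frozenset(planted_genes)))
    for i in range(1, cfg.n_pathways):
        size = int(rng.integers(10, 41))
        genes = frozenset(rng.choice(nodes, size=size, replace=False))
        gene_sets.append(PathwayGeneSet(f"PW{i:04d}", f"background pathway {i}", genes))

    truth = GroundTruth(
        planted_hubs=sorted(planted),
        intended_cti=intended,
        planted_pathway_id="PW0000",
        formula_targets=sorted(formula),
        disease_targets=sorted(disease),
        overlap_targets=sorted(overlap),
    )
    return FixtureBundle(
        config=cfg,
        compounds=compounds,
        ligand_sets=ligand_sets,
        known_cti=known,
        disease_targets=disease,
        drugs=drugs,
        ppi_edges=ppi_edges,
        gene_sets=gene_sets,
        ground_truth=truth,
    )


def ground_truth_report(bundle: FixtureBundle) -> dict:
    """Machine-readable ground truth for acceptance checks; JSON-stable."""
    return bundle.ground_truth.to_dict()


# ---------------------------------------------------------------------------
# file output


def write_fixture(bundle: FixtureBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write all fixture files in the pipeline's input dialects.

    Returns the path of every file written. Output is byte-deterministic
    for a fixed config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "compounds": out / "compounds.csv",
        "ligand_sets": out / "ligand_sets.tsv",
        "known_cti": out / "known_cti.tsv",
        "disease_targets": out / "disease_targets.txt",
        "drugs": out / "drugs.tsv",
        "ppi_edges": out / "ppi_edges.tsv",
        "gene_sets": out / "pathways.gmt",
        "ground_truth": out / "ground_truth.json",
    }
    with open(paths["compounds"], "w", encoding="utf-8") as fh:
        fh.write("compound_id,name,herb,fingerprint\n")
        for c in bundle.compounds:
            fh.write(f"{c.compound_id},{c.name},{c.herb},{format_fingerprint(c.fingerprint)}\n")
    with open(paths["ligand_sets"], "w", encoding="utf-8") as fh:
        fh.write("target_id\tfingerprint\n")
        for ls in bundle.ligand_sets:
            for fp in ls.ligands:
                fh.write(f"{ls.target_id}\t{format_fingerprint(fp)}\n")
    with open(paths["known_cti"], "w", encoding="utf-8") as fh:
        fh.write("compound_id\ttarget_id\n")
        for cid, tid in bundle.known_cti:
            fh.write(f"{cid}\t{tid}\n")
    with open(paths["disease_targets"], "w", encoding="utf-8") as fh:
        for t in sorted(bundle.disease_targets):
            fh.write(t + "\n")
    with open(paths["drugs"], "w", encoding="utf-8") as fh:
        fh.write("drug_id\tname\tdrug_class\ttargets\n")
        for d in bundle.drugs:
            fh.write(f"{d.drug_id}\t{d.name}\t{d.drug_class}\t{';'.join(sorted(d.targets))}\n")
    with open(paths["ppi_edges"], "w", encoding="utf-8") as fh:
        fh.write("protein_a\tprotein_b\tcombined_score\n")
        for e in bundle.ppi_edges:
            fh.write(f"{e.protein_a}\t{e.protein_b}\t{e.confidence:.3f}\n")
    write_gene_sets_gmt(bundle.gene_sets, paths["gene_sets"])
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        json.dump(ground_truth_report(bundle), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
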