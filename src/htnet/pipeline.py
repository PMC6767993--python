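"""End-to-end orchestration: predict -> merge -> overlap/drug-sharing ->
build-network -> screen -> enrich, composed through files so every
intermediate is inspectable.

Each stage failure aborts with the stage name; outputs carry a provenance
block (config echo + package version) and contain no timestamps, so
identical inputs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .enrichment import enrich
from .errors import PipelineError
from .hub_screening import screen
from .io_formats import (
    read_compound_table,
    read_drug_table,
    read_gene_list,
    read_gene_sets_gmt,
    read_ppi_edges,
    read_target_ligand_sets,
    write_gene_list,
    write_network,
)
from .network_build import build_network
from .target_prediction import (
    CTIRecord,
    drug_sharing,
    merge_cti,
    overlap_with_disease,
    predict_targets,
    target_universe,
)
from .topology import profile


@dataclass
class PipelineConfig:
    """Paths and parameters of one pipeline run (YAML-serializable)."""

    compounds: str
    ligand_sets: str
    known_cti: str
    disease_targets: str
    drugs: str
    ppi_edges: str
    gene_sets: str
    out_dir: str
    tc_threshold: float = 0.57
    min_confidence: float = 0.4
    hub_multiplier: float = 2.0
    metrics_scope: str = "hub-subnet"
    enrichment_method: str = "ease"
    enrichment_adjust: str = "benjamini_hochberg"
    score_dialect: str = "unit_interval"
    fingerprint_encoding: str = "bitstring"

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return PipelineConfig(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns (and writes) the run summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    @_stage("predict-targets")
    def _predict():
        compounds = read_compound_table(config.compounds, config.fingerprint_encoding)
        ligand_sets = read_target_ligand_sets(config.ligand_sets, config.fingerprint_encoding)
        predicted = predict_targets(compounds, ligand_sets, config.tc_threshold)
        known_pairs = []
        with open(config.known_cti, encoding="utf-8") as fh:
            header = fh.readline()
            for line in fh:
                cid, tid = line.split()
                known_pairs.append(CTIRecord(cid, tid.upper(), "known"))
        merged = merge_cti(known_pairs, predicted)
        with open(out / "cti.tsv", "w", encoding="utf-8") as fh:
            fh.write("compound_id\ttarget_id\tsource\tscore\n")
            for r in merged:
                score = "" if r.score is None else f"{r.score:.4f}"
                fh.write(f"{r.compound_id}\t{r.target_id}\t{r.source}\t{score}\n")
        return merged

    merged = _predict()
    formula_targets = target_universe(merged)
    write_gene_list(formula_targets, out / "formula_targets.txt")

    @_stage("disease-overlap")
    def _overlap():
        disease = read_gene_list(config.disease_targets)
        shared = overlap_with_disease(formula_targets, disease)
        write_gene_list(shared, out / "disease_overlap.txt")
        return disease, shared

    disease, shared = _overlap()

    @_stage("drug-sharing")
    def _drugs():
        drugs = read_drug_table(config.drugs)
        table = drug_sharing(formula_targets, drugs)
        table.to_csv(out / "drug_sharing.tsv", sep="\t", index=False)
        return table

    drug_table = _drugs()

    @_stage("build-network")
    def _network():
        edges = read_ppi_edges(config.ppi_edges, config.score_dialect)
        network = build_network(
            edges.edges, formula_targets, disease, config.min_confidence
        )
        write_network(network, out / "network.graphml", "graphml")
        write_network(network, out / "network.sif", "sif")
        return network

    network = _network()

    @_stage("topology")
    def _topology():
        profiles = profile(network)
        with open(out / "topology.tsv", "w", encoding="utf-8") as fh:
            fh.write("node\tdegree\tbetweenness\tcloseness\tkcore\n")
            for p in profiles:
                fh.write(f"{p.node}\t{p.degree}\t{p.betweenness:.6g}\t{p.closeness:.6g}\t{p.kcore}\n")
        return profiles

    _topology()

    @_stage("screen-hubs")
    def _screen():
        result = screen(network, config.hub_multiplier, config.metrics_scope)
        with open(out / "screen.json", "w", encoding="utf-8") as fh:
            json.dump(result.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return result

    screen_result = _screen()

    @_stage("enrich")
    def _enrich():
        gene_sets = read_gene_sets_gmt(config.gene_sets)
        report = enrich(
            screen_result.major_hubs,
            gene_sets,
            universe=None,
            method=config.enrichment_method,
            adjust=config.enrichment_adjust,
        ) if screen_result.major_hubs else None
        with open(out / "enrichment.tsv", "w", encoding="utf-8") as fh:
            fh.write(
                "pathway_id\tpathway_name\toverlap_count\tpathway_size\t"
                "query_size\tuniverse_size\tp_value\tp_adjusted\toverlap_genes\n"
            )
            if report is not None:
                for r in report:
                    fh.write(
                        f"{r.pathway_id}\t{r.pathway_name}\t{r.overlap_count}\t"
                        f"{r.pathway_size}\t{r.query_size}\t{r.universe_size}\t"
                        f"{r.p_value:.6g}\t{r.p_adjusted:.6g}\t"
                        f"{';'.join(sorted(r.overlap_genes))}\n"
                    )
        return report

    report = _enrich()

    summary = {
        "provenance": {"htnet_version": __version__, "config": config.to_dict()},
        "counts": {
            "cti_records": len(merged),
            "formula_targets": len(formula_targets),
            "disease_targets": len(disease),
            "disease_overlap": len(shared),
            "drugs_sharing_targets": int(len(drug_table)),
            "network_nodes": network.n_nodes,
            "network_edges": network.n_edges,
            "hubs": len(screen_result.hubs),
            "major_hubs": len(screen_result.major_hubs),
            "formula_major_hubs": len(screen_result.formula_major_hubs),
            "pathways_enriched": 0 if report is None else len(report),
        },
        "top_pathway": None
        if report is None or not len(report)
        else {
            "pathway_id": report[0].pathway_id,
            "p_value": report[0].p_value,
            "overlap_count": report[0].overlap_count,
        },
    }
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
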