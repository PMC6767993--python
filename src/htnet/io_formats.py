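"""Readers and writers for every external representation the pipeline touches.

Tables are CSV/TSV with a header row (separator sniffed), gene-set
collections are GMT, and networks are exported as GraphML, SIF or a
two-block TSV. All identifiers that live in the shared protein/gene symbol
namespace are canonicalized by trimming whitespace and uppercasing; no
symbol aliasing is attempted. Every discarded row increments a counter
exposed on the returned result object — readers never coerce silently.

Fingerprints are fixed-length binary vectors supplied by the caller, not
computed from structures; two cell encodings are supported:

* ``bitstring`` — e.g. ``"00110"`` sets bits {2, 3} (0-based positions).
* ``index_list`` — ``"<L>:<i>,<j>,..."``, e.g. ``"16:2,5"`` is a length-16
  vector with bits 2 and 5 set (``"16:"`` is the all-zero vector).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

log = logging.getLogger(__name__)

Fingerprint = np.ndarray  # 1-D uint8 array of 0/1

FingerprintEncoding = Literal["bitstring", "index_list"]
ScoreDialect = Literal["unit_interval", "string_0_999"]
NetworkFormat = Literal["graphml", "sif", "tsv"]


def canonical_symbol(symbol: str) -> str:
    """Canonical form of a gene/protein symbol: trimmed and uppercased."""
    return symbol.strip().upper()


# ---------------------------------------------------------------------------
# domain records


@dataclass(eq=False)
class CompoundRecord:
    """One formula constituent with a binary fingerprint."""

    compound_id: str
    name: str
    herb: str
    fingerprint: Fingerprint

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CompoundRecord):
            return NotImplemented
        return (
            self.compound_id == other.compound_id
            and self.name == other.name
            and self.herb == other.herb
            and np.array_equal(self.fingerprint, other.fingerprint)
        )

    def __hash__(self) -> int:
        return hash(self.compound_id)


@dataclass(eq=False)
class TargetLigandSet:
    """Reference ligands of one target, against which similarity is scored."""

    target_id: str
    ligands: list[Fingerprint]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TargetLigandSet):
            return NotImplemented
        if self.target_id != other.target_id or len(self.ligands) != len(other.ligands):
            return False
        return all(np.array_equal(a, b) for a, b in zip(self.ligands, other.ligands))


@dataclass(frozen=True)
class PPIEdgeRecord:
    """A confidence-weighted protein-protein interaction, canonically ordered."""

    protein_a: str
    protein_b: str
    confidence: float

    @staticmethod
    def make(a: str, b: str, confidence: float) -> "PPIEdgeRecord":
        a, b = canonical_symbol(a), canonical_symbol(b)
        if a > b:
            a, b = b, a
        return PPIEdgeRecord(a, b, confidence)

    @property
    def key(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)


@dataclass(frozen=True)
class PathwayGeneSet:
    pathway_id: str
    pathway_name: str
    genes: frozenset[str]


@dataclass(frozen=True)
class DrugRecord:
    drug_id: str
    name: str
    drug_class: str  # DMARD | NSAID | other
    targets: frozenset[str]


DRUG_CLASSES = {"DMARD", "NSAID", "other"}


# ---------------------------------------------------------------------------
# fingerprints


def parse_fingerprint(
    cell: str,
    encoding: FingerprintEncoding,
    expected_length: int | None = None,
    row: int | None = None,
) -> Fingerprint:
    """Parse one fingerprint cell; enforce ``expected_length`` if given."""
    where = f" (row {row})" if row is not None else ""
    cell = cell.strip()
    if encoding == "bitstring":
        if not cell or set(cell) - {"0", "1"}:
            raise FormatError(f"invalid bitstring fingerprint {cell!r}{where}")
        fp = np.array([c == "1" for c in cell], dtype=np.uint8)
    elif encoding == "index_list":
        head, sep, tail = cell.partition(":")
        if not sep:
            raise FormatError(
                f"index_list fingerprint must look like 'L:i,j,...', got {cell!r}{where}"
            )
        try:
            length = int(head)
            bits = [int(tok) for tok in tail.split(",") if tok.strip() != ""]
        except ValueError as exc:
            raise FormatError(f"unparseable index_list fingerprint {cell!r}{where}") from exc
        if length < 1 or any(b < 0 or b >= length for b in bits):
            raise ValidationError(f"fingerprint bit index out of range in {cell!r}{where}")
        fp = np.zeros(length, dtype=np.uint8)
        fp[bits] = 1
    else:
        raise ValueError(f"unknown fingerprint encoding {encoding!r}")
    if expected_length is not None and fp.size != expected_length:
        raise ValidationError(
            f"fingerprint length {fp.size} != table length {expected_length}{where}"
        )
    return fp


def format_fingerprint(fp: Fingerprint, encoding: FingerprintEncoding = "bitstring") -> str:
    if encoding == "bitstring":
        return "".join("1" if b else "0" for b in fp)
    bits = ",".join(str(i) for i in np.flatnonzero(fp))
    return f"{fp.size}:{bits}"


# ---------------------------------------------------------------------------
# table readers


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    """Sniffed-separator table read with a column-presence check."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df


def read_compound_table(
    path: str | Path, fingerprint_encoding: FingerprintEncoding = "bitstring"
) -> list[CompoundRecord]:
    """Read a compound table with columns compound_id, name, herb, fingerprint.

    Fingerprint length L is inferred from the first row and enforced on all
    subsequent rows; duplicate compound ids are rejected.
    """
    df = _read_table(path, ["compound_id", "name", "herb", "fingerprint"])
    records: list[CompoundRecord] = []
    seen: set[str] = set()
    length: int | None = None
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        cid = row.compound_id.strip()
        if not cid:
            raise ValidationError(f"{path}: empty compound_id (row {i})")
        if cid in seen:
            raise ValidationError(f"{path}: duplicate compound_id {cid!r} (row {i})")
        seen.add(cid)
        fp = parse_fingerprint(row.fingerprint, fingerprint_encoding, length, row=i)
        if length is None:
            length = fp.size
            if length < 16:
                raise ValidationError(f"{path}: fingerprint length {length} < 16")
        records.append(CompoundRecord(cid, row.name.strip(), row.herb.strip(), fp))
    return records


def read_target_ligand_sets(
    path: str | Path, fingerprint_encoding: FingerprintEncoding = "bitstring"
) -> list[TargetLigandSet]:
    """Read per-target ligand fingerprints (columns target_id, fingerprint;
    one ligand per row, grouped by target)."""
    df = _read_table(path, ["target_id", "fingerprint"])
    by_target: dict[str, list[Fingerprint]] = {}
    length: int | None = None
    for i, row in enumerate(df.itertuples(index=False), start=2):
        tid = canonical_symbol(row.target_id)
        if not tid:
            raise ValidationError(f"{path}: empty target_id (row {i})")
        fp = parse_fingerprint(row.fingerprint, fingerprint_encoding, length, row=i)
        length = fp.size if length is None else length
        by_target.setdefault(tid, []).append(fp)
    return [TargetLigandSet(tid, fps) for tid, fps in by_target.items()]


@dataclass
class PPIReadResult:
    """Edges plus the counters for everything the reader discarded."""

    edges: list[PPIEdgeRecord]
    self_loops_dropped: int = 0
    duplicates_collapsed: int = 0

    def __iter__(self) -> Iterator[PPIEdgeRecord]:
        return iter(self.edges)

    def __len__(self) -> int:
        return len(self.edges)


def read_ppi_edges(
    path: str | Path, score_dialect: ScoreDialect = "unit_interval"
) -> PPIReadResult:
    """Read a STRING-style edge list (whitespace- or tab-separated triplets).

    ``string_0_999`` scores are integers in [0, 999] and are divided by 1000;
    ``unit_interval`` scores are reals in [0, 1]. Self-loops are dropped and
    duplicate unordered pairs collapsed keeping the maximum confidence, with
    both events counted on the result.
    """
    best: dict[tuple[str, str], float] = {}
    self_loops = 0
    duplicates = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or line.lstrip().startswith("#"):
                continue
            if len(parts) != 3:
                raise FormatError(f"{path}: expected 3 fields, got {len(parts)} (line {lineno})")
            a, b, raw = parts
            try:
                score = float(raw)
            except ValueError:
                if lineno == 1:  # tolerate a header line
                    continue
                raise FormatError(f"{path}: unparseable score {raw!r} (line {lineno})")
            if score_dialect == "string_0_999":
                if not (0 <= score <= 999):
                    raise ValidationError(
                        f"{path}: score {raw} outside [0, 999] (line {lineno})"
                    )
                confidence = score / 1000.0
            elif score_dialect == "unit_interval":
                if not (0.0 <= score <= 1.0):
                    raise ValidationError(f"{path}: score {raw} outside [0, 1] (line {lineno})")
                confidence = score
            else:
                raise ValueError(f"unknown score dialect {score_dialect!r}")
            edge = PPIEdgeRecord.make(a, b, confidence)
            if edge.protein_a == edge.protein_b:
                self_loops += 1
                continue
            if edge.key in best:
                duplicates += 1
                best[edge.key] = max(best[edge.key], confidence)
            else:
                best[edge.key] = confidence
    if self_loops or duplicates:
        log.info(
            "read_ppi_edges(%s): dropped %d self-loops, collapsed %d duplicate pairs",
            path, self_loops, duplicates,
        )
    edges = [PPIEdgeRecord(a, b, c) for (a, b), c in best.items()]
    return PPIReadResult(edges, self_loops, duplicates)


def read_gene_sets_gmt(path: str | Path) -> list[PathwayGeneSet]:
    """Read a GMT collection: ``name TAB description TAB gene TAB gene...``"""
    sets: list[PathwayGeneSet] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: GMT line with < 3 fields (line {lineno})")
            pathway_id = fields[0].strip()
            if pathway_id in seen:
                raise ValidationError(f"{path}: duplicate pathway_id {pathway_id!r} (line {lineno})")
            seen.add(pathway_id)
            genes = frozenset(canonical_symbol(g) for g in fields[2:] if g.strip())
            if not genes:
                raise FormatError(f"{path}: empty gene set {pathway_id!r} (line {lineno})")
            sets.append(PathwayGeneSet(pathway_id, fields[1].strip(), genes))
    return sets


def write_gene_sets_gmt(sets: Sequence[PathwayGeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.pathway_id, s.pathway_name, *sorted(s.genes)]) + "\n")


def read_drug_table(path: str | Path) -> list[DrugRecord]:
    """Read drugs with columns drug_id, name, drug_class, targets
    (semicolon-separated gene symbols)."""
    df = _read_table(path, ["drug_id", "name", "drug_class", "targets"])
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        cls = row.drug_class.strip()
        if cls not in DRUG_CLASSES:
            raise ValidationError(f"{path}: unknown drug_class {cls!r} (row {i})")
        targets = frozenset(
            canonical_symbol(t) for t in row.targets.split(";") if t.strip()
        )
        if not targets:
            raise ValidationError(f"{path}: drug {row.drug_id!r} has no targets (row {i})")
        records.append(DrugRecord(row.drug_id.strip(), row.name.strip(), cls, targets))
    return records


def read_gene_list(path: str | Path) -> set[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(canonical_symbol(line))
    return out


def write_gene_list(genes: set[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


# ---------------------------------------------------------------------------
# network export / import


def write_network(network, path: str | Path, format: NetworkFormat = "graphml") -> None:
    """Export a network for downstream visualization (Cytoscape-compatible).

    GraphML and TSV round-trip node flags, edge confidences and node sets
    exactly; SIF is a lossy edge-only export.
    """
    import networkx as nx

    graph = network.graph
    if format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for a, b in sorted(graph.edges()):
                fh.write(f"{a}\tpp\t{b}\n")
            for node in sorted(nx.isolates(graph)):
                fh.write(f"{node}\n")
    elif format == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("record\tfield1\tfield2\tfield3\n")
            for node in sorted(graph.nodes()):
                d = graph.nodes[node]
                fh.write(
                    "node\t%s\t%d\t%d\n"
                    % (node, int(d.get("is_formula_target", False)),
                       int(d.get("is_disease_target", False)))
                )
            for a, b in sorted(graph.edges()):
                fh.write("edge\t%s\t%s\t%r\n" % (a, b, graph.edges[a, b]["confidence"]))
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: NetworkFormat = "graphml"):
    """Inverse of :func:`write_network` for the lossless formats."""
    import networkx as nx

    from .network_build import InteractionNetwork  # local import: avoids cycle

    if format == "graphml":
        graph = nx.read_graphml(path)
        clean = nx.Graph()
        for node, d in graph.nodes(data=True):
            clean.add_node(
                str(node),
                is_formula_target=bool(d.get("is_formula_target", False)),
                is_disease_target=bool(d.get("is_disease_target", False)),
            )
        for a, b, d in graph.edges(data=True):
            clean.add_edge(str(a), str(b), confidence=float(d["confidence"]))
        return InteractionNetwork(clean)
    if format == "tsv":
        graph = nx.Graph()
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            if not header.startswith("record\t"):
                raise FormatError(f"{path}: not a network TSV (bad header)")
            for lineno, line in enumerate(fh, start=2):
                fields = line.rstrip("\n").split("\t")
                if fields[0] == "node":
                    graph.add_node(
                        fields[1],
                        is_formula_target=bool(int(fields[2])),
                        is_disease_target=bool(int(fields[3])),
                    )
                elif fields[0] == "edge":
                    graph.add_edge(fields[1], fields[2], confidence=float(fields[3]))
                else:
                    raise FormatError(f"{path}: unknown record type {fields[0]!r} (line {lineno})")
        return InteractionNetwork(graph)
    raise ValueError(f"cannot read network format {format!r}")
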