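"""Similarity-based compound-target prediction and target-set comparisons.

Candidate targets are scored by the Tanimoto coefficient (Tc) between a
compound's binary fingerprint and each reference ligand of a target,
aggregated by max over the ligand set; a compound-target pair is predicted
iff its max-Tc meets the confidence threshold (default 0.57). Predicted
interactions are merged with curated ones (curated wins on collision), and
the resulting formula target set is compared against disease target lists
and approved-drug target sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import (
    CompoundRecord,
    DrugRecord,
    Fingerprint,
    TargetLigandSet,
    canonical_symbol,
)

DEFAULT_TC_THRESHOLD = 0.57


@dataclass(frozen=True)
class CTIRecord:
    """A compound-target interaction, curated (``known``) or ``predicted``.

    ``score`` is the max-Tc for predictions and ``None`` for curated links;
    after a merge collision a curated record keeps the prediction's score as
    an annotation.
    """

    compound_id: str
    target_id: str
    source: str  # "known" | "predicted"
    score: float | None = None

    @property
    def key(self) -> tuple[str, str]:
        return (self.compound_id, self.target_id)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| of two binary vectors.

    Both-all-zero pairs score 0 by convention so degenerate fingerprints are
    filterable rather than NaN.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValidationError(f"fingerprint length mismatch: {a.size} vs {b.size}")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return 0.0
    return int(np.logical_and(a, b).sum()) / union


def predict_targets(
    compounds: Sequence[CompoundRecord],
    ligand_sets: Sequence[TargetLigandSet],
    tc_threshold: float = DEFAULT_TC_THRESHOLD,
    aggregation: str = "max",
) -> list[CTIRecord]:
    """Predict CTIs: for every (compound, target) pair, score = max Tc over
    the target's ligands; emit the pair iff score >= ``tc_threshold``."""
    if not ligand_sets:
        raise ValidationError("ligand set list is empty")
    if not (0.0 < tc_threshold <= 1.0):
        raise ValidationError(f"tc_threshold {tc_threshold} outside (0, 1]")
    if aggregation != "max":
        raise ValidationError(f"unknown aggregation {aggregation!r}")
    for ls in ligand_sets:
        if not ls.ligands:
            raise ValidationError(f"target {ls.target_id!r} has an empty ligand set")

    # stack each target's ligands once; scoring is then a vectorized pass
    records: list[CTIRecord] = []
    stacked = [
        (ls.target_id, np.asarray(ls.ligands, dtype=bool)) for ls in ligand_sets
    ]
    for comp in compounds:
        fp = np.asarray(comp.fingerprint, dtype=bool)
        for target_id, ligands in stacked:
            if ligands.shape[1] != fp.size:
                raise ValidationError(
                    f"fingerprint length mismatch: compound {comp.compound_id!r} "
                    f"({fp.size}) vs ligands of {target_id!r} ({ligands.shape[1]})"
                )
            inter = np.logical_and(ligands, fp).sum(axis=1)
            union = np.logical_or(ligands, fp).sum(axis=1)
            with np.errstate(invalid="ignore"):
                tc = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
            score = float(tc.max())
            if score >= tc_threshold:
                records.append(
                    CTIRecord(comp.compound_id, target_id, "predicted", score)
                )
    return records


def merge_cti(
    known: Iterable[CTIRecord], predicted: Iterable[CTIRecord]
) -> list[CTIRecord]:
    """Union keyed by (compound, target); curated records win collisions,
    keeping the prediction's score as an annotation."""
    merged: dict[tuple[str, str], CTIRecord] = {}
    for rec in known:
        merged[rec.key] = rec
    for rec in predicted:
        if rec.key in merged:
            prior = merged[rec.key]
            merged[rec.key] = CTIRecord(
                prior.compound_id, prior.target_id, prior.source, rec.score
            )
        else:
            merged[rec.key] = rec
    return sorted(merged.values(), key=lambda r: r.key)


def target_universe(cti: Iterable[CTIRecord]) -> set[str]:
    """Distinct target ids carried by a CTI collection."""
    return {r.target_id for r in cti}


def overlap_with_disease(cti_targets: set[str], disease_targets: set[str]) -> set[str]:
    """Formula targets that are also disease targets (exact intersection)."""
    return {canonical_symbol(t) for t in cti_targets} & {
        canonical_symbol(t) for t in disease_targets
    }


def drug_sharing(
    formula_targets: set[str], drugs: Sequence[DrugRecord]
) -> pd.DataFrame:
    """Per-drug shared-target counts against the formula target set.

    Drugs with no shared target are omitted; rows are sorted by shared count
    descending, then drug name ascending.
    """
    formula = {canonical_symbol(t) for t in formula_targets}
    rows = []
    for drug in drugs:
        shared = drug.targets & formula
        if shared:
            rows.append(
                {
                    "drug_id": drug.drug_id,
                    "name": drug.name,
                    "shared_targets": len(shared),
                    "drug_class": drug.drug_class,
                    "shared_genes": ";".join(sorted(shared)),
                }
            )
    df = pd.DataFrame(
        rows, columns=["drug_id", "name", "shared_targets", "drug_class", "shared_genes"]
    )
    if len(df):
        df = df.sort_values(
            ["shared_targets", "name"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
    return df
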