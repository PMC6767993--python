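#!/usr/bin/env python
"""Predict compound-target interactions and assemble the formula target set.

Scores every compound against every reference ligand set by max-Tanimoto
similarity, keeps pairs at Tc >= 0.57, merges them with the curated links
(curated wins on collision), and writes the combined interaction table and
the distinct formula target list to results/.
"""

from pathlib import Path

from htnet.io_formats import read_compound_table, read_target_ligand_sets, write_gene_list
from htnet.target_prediction import CTIRecord, merge_cti, predict_targets, target_universe

root = Path(__file__).resolve().parents[1] / "results"
fix = root / "fixture"

compounds = read_compound_table(fix / "compounds.csv")
ligand_sets = read_target_ligand_sets(fix / "ligand_sets.tsv")
predicted = predict_targets(compounds, ligand_sets, tc_threshold=0.57)

known = []
with open(fix / "known_cti.tsv") as fh:
    fh.readline()
    for line in fh:
        cid, tid = line.split()
        known.append(CTIRecord(cid, tid, "known"))

merged = merge_cti(known, predicted)
targets = target_universe(merged)

with open(root / "cti.tsv", "w") as fh:
    fh.write("compound_id\ttarget_id\tsource\tscore\n")
    for r in merged:
        fh.write(f"{r.compound_id}\t{r.target_id}\t{r.source}\t"
                 f"{'' if r.score is None else f'{r.score:.4f}'}\n")
write_gene_list(targets, root / "formula_targets.txt")

print(f"{len(predicted)} interactions predicted at Tc >= 0.57 "
      f"for {len({r.target_id for r in predicted})} targets")
print(f"{len(known)} curated interactions merged in "
      f"-> {len(merged)} unique compound-target pairs")
print(f"formula target universe: {len(targets)} proteins -> results/formula_targets.txt")
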