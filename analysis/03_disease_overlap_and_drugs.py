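#!/usr/bin/env python
"""Compare the formula target set with disease targets and approved drugs.

Intersects the formula targets with the disease target list, then counts,
for every approved drug, how many of its targets the formula also hits —
the shared-target table that suggests which drug classes the formula's
action profile resembles.
"""

from pathlib import Path

from htnet.io_formats import read_drug_table, read_gene_list, write_gene_list
from htnet.target_prediction import drug_sharing, overlap_with_disease

root = Path(__file__).resolve().parents[1] / "results"
fix = root / "fixture"

formula = read_gene_list(root / "formula_targets.txt")
disease = read_gene_list(fix / "disease_targets.txt")
shared = overlap_with_disease(formula, disease)
write_gene_list(shared, root / "disease_overlap.txt")

drugs = read_drug_table(fix / "drugs.tsv")
table = drug_sharing(formula, drugs)
table.to_csv(root / "drug_sharing.tsv", sep="\t", index=False)

print(f"{len(shared)} of {len(disease)} disease targets are hit by the formula")
print(f"{len(table)} of {len(drugs)} approved drugs share >= 1 target with the formula")
if len(table):
    top = table.iloc[0]
    print(f"top drug: {top['name']} ({top['drug_class']}) "
          f"sharing {top['shared_targets']} targets")
    by_class = table.groupby("drug_class")["drug_id"].count().to_dict()
    print(f"by class: {by_class}")
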