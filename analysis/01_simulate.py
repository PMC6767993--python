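#!/usr/bin/env python
"""Generate the synthetic study inputs.

Writes the default fixture bundle — 800 compounds over ten herbs, reference
ligand sets, curated compound-target links, disease targets, approved
drugs, a 300-protein STRING-dialect edge list with planted hubs, and a
pathway collection with one planted set — to results/fixture/, together
with the machine-readable ground truth of everything planted.
"""

import json
from pathlib import Path

from htnet.synthetic_data import GeneratorConfig, generate_fixture, write_fixture

SEED = 2019

out_dir = Path(__file__).resolve().parents[1] / "results" / "fixture"
bundle = generate_fixture(GeneratorConfig(seed=SEED))
paths = write_fixture(bundle, out_dir)

truth = bundle.ground_truth
print(f"fixture written to {out_dir} (seed {SEED})")
print(f"  compounds:        {len(bundle.compounds)}")
print(f"  ligand-set targets: {len(bundle.ligand_sets)}")
print(f"  curated CTIs:     {len(bundle.known_cti)}")
print(f"  intended predicted CTIs: {len(truth.intended_cti)}")
print(f"  disease targets:  {len(bundle.disease_targets)} "
      f"({len(truth.overlap_targets)} also formula targets)")
print(f"  PPI edges:        {len(bundle.ppi_edges)}")
print(f"  planted hubs:     {len(truth.planted_hubs)}")
print(f"  pathways:         {len(bundle.gene_sets)} "
      f"(planted: {truth.planted_pathway_id})")
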