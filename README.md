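# htnet

Network-pharmacology analysis of multi-herb formulas: which proteins do a
formula's chemical constituents touch, how central are those proteins in
the disease-relevant protein–protein interaction (PPI) network, and which
pathways do the most central ones populate?

The package implements the complete dry-lab workflow as a tested library
with a CLI, exercised end-to-end on synthetic inputs with planted,
verifiable structure:

1. **Target prediction** — a compound–target interaction is predicted when
   the max-Tanimoto similarity of the compound's fingerprint to the
   target's reference ligands meets the confidence cut, Tc ≥ 0.57 by
   default; predictions are merged with curated interactions (curation
   wins collisions).
2. **Target-set comparisons** — exact overlap with a disease target list;
   per-drug shared-target counts against approved drugs.
3. **Network construction** — STRING-dialect edges filtered at medium
   confidence (combined score ≥ 0.400) between formula/disease targets.
4. **Two-stage hub screen** — *hubs*: degree strictly > 2× the median
   degree of all nodes; *major hubs*: hubs strictly above the
   hub-subnetwork medians of all four indicators — degree, betweenness,
   closeness, k-core — simultaneously.
5. **Pathway enrichment** — exact hypergeometric upper tail or the
   conservative EASE variant (tail at k−1), Benjamini–Hochberg corrected.

See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

The `analysis/` scripts run the whole study on a generated fixture:

```bash
python analysis/01_simulate.py
python analysis/02_predict_targets.py
python analysis/03_disease_overlap_and_drugs.py
python analysis/04_network_and_hub_screen.py
python analysis/05_pathway_enrichment.py
```

which prints (seed 2019):

```
81 interactions predicted at Tc >= 0.57 for 40 targets
349 curated interactions merged in -> 430 unique compound-target pairs
formula target universe: 212 proteins -> results/formula_targets.txt
...
12 of 100 disease targets are hit by the formula
21 of 23 approved drugs share >= 1 target with the formula
...
network: 300 nodes, 2742 edges (0 self-loops dropped)
degree median 15 -> hub threshold 30
hubs: 12 (planted 12; recovered exactly: True)
major hubs: 6 (6 are formula targets)
narrowing pattern: 300 nodes -> 12 hubs -> 6 major hubs -> 6 formula-targeted
...
top pathway: PW0000 (planted pathway), overlap 6/20, EASE p = 6.09e-06, BH-adjusted 0.000183
planted pathway ranks first: True
```

Reading: of 800 compounds, the similarity rule plus curated links yield
212 distinct formula targets; 12 are also disease targets; the 300-protein
network narrows to 12 degree-hubs and then to 6 major hubs, all of them
formula targets; and the pathway planted around the hubs tops the
enrichment ranking — the same screening funnel the method applies to real
database inputs.

The same workflow is available as subcommands:

```bash
htnet simulate --seed 2019 --out-dir fixture/
htnet run --config run.yaml
htnet predict-targets --compounds fixture/compounds.csv \
      --ligand-sets fixture/ligand_sets.tsv --tc-threshold 0.57 --out cti.tsv
```

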