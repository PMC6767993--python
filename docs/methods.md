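# Methods

`htnet` implements the dry-lab arm of a network-pharmacology study of a
multi-herb formula: which proteins do the formula's constituents touch, how
do those proteins sit in the disease-relevant interaction network, and
which pathways do the network's most central proteins populate. This note
records the models, conventions and design choices behind each stage, and
what the synthetic study conditions do and do not demonstrate.

## Compound-target prediction

Each compound carries a fixed-length binary fingerprint (an abstract bit
vector; the package computes none from structures). A candidate target is
represented by a set of reference ligand fingerprints. The similarity of a
compound to a target is the maximum Tanimoto coefficient

    Tc(a, b) = |a AND b| / |a OR b|

over the target's ligands, and a compound-target interaction is predicted
iff that max-Tc meets the confidence cut, default **Tc >= 0.57**. Two
conventions matter:

* a pair of all-zero fingerprints scores 0, not NaN, so degenerate
  compounds are filterable rather than fatal;
* aggregation over a ligand set is the max statistic only. Ensemble
  approaches additionally calibrate a raw-score sum against random-pair
  distributions to obtain an E-value; since the screen here is defined
  purely by a Tc cut, that machinery is deliberately out of scope and the
  `aggregation` argument leaves room for alternatives.

The meaning of any fixed Tc cut depends on the fingerprint type and length,
so both the length `L` and the threshold are free configuration rather than
constants.

Predicted interactions are merged with curated ones keyed by
(compound, target). Curated records win collisions — curation outranks
similarity — but the prediction's score is retained as an annotation. The
formula target set is the distinct targets of the merged table.

## Target-set comparisons

Disease overlap is an exact set intersection after symbol
canonicalization (trim + uppercase; no alias resolution, because no
mapping table is part of the inputs — the pipeline assumes one shared
symbol namespace across compound, interaction and pathway sources).
Drug sharing counts |drug targets ∩ formula targets| per approved drug,
omits drugs sharing nothing, and sorts by shared count descending with
name as tie-break.

## Network construction

PPI edges arrive STRING-style: unordered protein pairs with a combined
confidence, accepted either as 0-999 integers (divided by 1000) or as
[0, 1] reals, selected explicitly by a dialect flag. Readers drop
self-loops and collapse duplicate unordered pairs keeping the maximum
confidence; every discarded row increments a counter exposed to the
caller, never a silent coercion.

The analysis network keeps edges with confidence >= `min_confidence`
(default **0.400**, the STRING developers' published "medium confidence"
cut) whose endpoints are both formula or disease targets. Nodes carry
membership flags for both sets. Proteins with no surviving edge are
excluded by default: a degree-0 node can never be a hub, and keeping
isolates would only depress the degree median that the hub rule divides
the network by. Because that median shift is a real modelling choice, a
`keep_isolated` switch retains them for sensitivity analysis.

## Topological indicators

Computed on the unweighted simple graph (confidences weight admission,
not distance — weighted centralities are not part of this design):

* **degree** — incident edge count;
* **betweenness** — endpoint-excluded shortest-path betweenness with
  fractional counting over equal-length paths, normalized by
  (n-1)(n-2)/2. Normalization is the default because it makes values
  comparable across networks of different size; the unnormalized variant
  is available behind a flag and recorded in output, since screening
  traditions differ on this convention;
* **closeness** — reachability-weighted: a node with r reachable others
  at total distance S scores (r/S)(r/(n-1)). On a connected graph this is
  the classical (n-1)/S; on a disconnected one it stays finite and
  penalizes small components instead of dividing by infinity;
* **k-core index** — the largest k such that the node survives iterative
  minimum-degree peeling.

All four are delegated to networkx and verified, in the test suite,
against hand-written oracles (explicit BFS path enumeration, exhaustive
peeling) exactly on hundreds of small random graphs.

## Two-stage hub screen

Stage 1: a **hub** is a node whose degree strictly exceeds
`multiplier x median(degree over all nodes)`, default multiplier 2.
Medians over an even count are the mean of the two central order
statistics (hence fractional thresholds are normal).

Stage 2: the four indicators are recomputed **on the hub-induced
subnetwork**, their medians taken over the hub set, and a **major hub**
must be strictly greater than all four medians simultaneously.
Strict inequality is the deliberate reading of "higher than the median":
it makes the all-tied case well defined (zero major hubs) and bounds
survivors by half the hub set per indicator. Scoring hubs on the full
network instead is available via `metrics_scope="full"` since either
scoping is defensible; the hub-subnetwork scope is the default because
the second stage is explicitly a screen *of the hub network*.

The screen is a pure function of the network — no randomness, no order
dependence — so repeated runs are bit-identical.

## Pathway over-representation

For a query of n genes from a universe of N, a pathway with K genes and
overlap k is scored by the exact hypergeometric upper tail
P(X >= k), summed in integer arithmetic (`math.comb`) and divided once,
so small p-values carry no accumulation error. The default statistic is
the **EASE score**: the same tail evaluated at k-1, the conservative
variant used by the DAVID annotation service, under which single-gene
overlaps are never significant. The plain tail is available as
`method="hypergeometric"`.

The universe defaults to the union of the loaded collection — an
explicit, reproducible choice documented in every result row
(`universe_size`) because annotation services rarely state their
background. Benjamini-Hochberg step-up correction (statsmodels) is the
default; `adjust="none"` reproduces raw-p presentations. P-values are
computed for every pathway with a nonempty universe-intersected gene set
and adjusted across all of them; only pathways with overlap >= 1 are
reported, sorted by p ascending with pathway id as tie-break.

## Synthetic study conditions

The generator emulates the statistical shape of the real inputs so the
pipeline is exercisable and testable offline. Defaults, chosen once to
mirror a ten-herb formula study at desk scale:

| parameter | default | what it emulates |
|---|---|---|
| n_compounds | 800 | constituents of a ten-herb formula |
| fingerprint_length / density | 64 / 0.3 | abstract structural keys |
| n_targets (ligand sets) | 40 | similarity-predictable targets |
| n_disease_targets | 100 | disease gene list |
| overlap_fraction | 0.12 | formula-disease target overlap rate |
| n_background_nodes + n_planted_hubs | 288 + 12 | PPI layer (300 proteins) |
| edge_prob_background | 0.04 | Erdos-Renyi interaction background |
| hub_degree_boost | 80 | planted hub degree (vs threshold ~30) |
| confidence_range | (0.4, 1.0) | STRING combined scores above medium |
| n_pathways / planted_pathway_overlap | 30 / 12 | pathway collection with one planted set |
| n_drugs / n_dmards | 23 / 4 | approved-drug table |

Planted hubs are wired to random background partners far above the
2x-median threshold; among themselves they form two deterministic tiers —
a core clique with the remaining hubs attached as single pendants — so
the hub-induced subnetwork separates cleanly on all four indicators and
the strict major-hub rule has a nonempty proper solution. Designated
active compounds copy (or lightly mutate) a ligand fingerprint of their
intended target so their max-Tc provably meets the cut.

**Planting is verified, not attempted**: before returning, the generator
runs the hub rule on its own output and trims/boosts background edges
until the planted set is recovered exactly, and re-randomizes any
compound whose fingerprint accidentally crosses the similarity threshold
for an unintended target. Repairs are bounded; an infeasible
configuration raises before any file is written. One integer seed drives
all randomness through a single NumPy generator; equal seeds give
byte-identical files.

What the fixtures do **not** emulate: real chemistry (fingerprints are
abstract bits, so the Tc = 0.57 cut is exercised, not validated),
scale-free degree distributions (hubs are planted on an ER background,
not grown), gene-symbol aliasing, correlated pathway membership, and
database-version effects. Tests passing on these fixtures demonstrate
that the algorithms implement their definitions and recover known
structure — not that any particular biological count would reproduce.

## Numerical and degenerate-input choices

* Medians: arithmetic mean of central order statistics (`statistics.median`).
* Hypergeometric tails: exact integer sums; validation rejects
  inconsistent (k, n, K, N) rather than clamping.
* Empty network: valid for construction and export, rejected by the
  screen (no median exists).
* Empty hub set: stage 2 refuses; the composed screen returns an empty
  result instead when stage 1 finds nothing.
* Ties: every comparison in both screening stages is strict; nothing is
  broken by randomness anywhere in the pipeline.
* Problem sizes in the shipped analysis and test suite (300-node
  networks, 200 twelve-node oracle graphs, 50 x 20 prediction fixtures)
  are the package's chosen desk scale: large enough to exhibit every
  structural pattern, small enough that the whole suite runs in seconds.

## Known limitations

* One shared symbol namespace is assumed across all inputs; no alias
  resolution.
* Max-Tc is the only ligand-set aggregation implemented.
* Centralities are exact, not sampled; very large networks would need
  approximate betweenness, which is out of scope at desk scale.
* The EASE/hypergeometric pair covers single-list over-representation
  only — no term graphs, no modular clustering of terms.
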