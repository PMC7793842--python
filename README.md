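# hgpm — hierarchical graphs of pharmacophore model ensembles

`hgpm` turns large ensembles of interaction-based pharmacophore models —
typically one model per frame of a protein–ligand molecular-dynamics
trajectory — into a single interactive hierarchical graph, and drives
pharmacophore-model selection and consensus virtual-screening scoring from
that graph. It is aimed at computational chemists who have thousands of
frame-derived models and need to prioritise a small, well-performing subset
for screening campaigns without a labelled activity dataset.

## The method

Each pharmacophore feature is identified purely by composition — interaction
type (hydrophobic `H`, aromatic `AR`, H-bond acceptor/donor `HBA`/`HBD`,
ionizable `PI`/`NI`, halogen-bond donor `XBD`), the ligand atoms involved,
and the interacting protein residues — never by 3D position. Every frame's
model becomes a binary **feature vector** over the catalog of all unique
features, duplicates are merged with an **appearance count**, and rare
vectors are filtered (count ≥ 2, or ≥ ⌊f·N⌋ for a fraction f of N frames).

The surviving vectors are linked into the Hasse diagram of the strict-subset
order: an edge u → v means u's feature set is contained in v's with nothing
in between. Whenever two nodes are incomparable, the intersection of their
feature sets is inserted as an **artificial node** with appearance count 0
(unless an equal node exists), and this closure is run to a fixpoint, so the
node family is closed under pairwise non-empty intersection and the graph is
independent of input order. The layout is deterministic: x = number of
features (specificity), y = one-dimensional classical (Torgerson) MDS of the
pairwise Manhattan distances between feature vectors, with the eigenvalue
ratio 100·λ₁/Σλ₊ reported as the variance of the projection.

Selections are phrased on the graph — the highest-frequency (HF) node, the
node of a crystal-structure model, a common-features (CF) node, or all
observed supersets of such an anchor (HF+, CF+) — and screened through each
node's representative model (the first frame observed with that vector).
Per-model hit lists combine by the common-hits consensus count, and
performance is summarised as ROC AUC truncated at a percentage of the
screened database (early enrichment).

A synthetic-data module generates MD-like ensembles (per-feature two-state
Markov chains with exact stationary probabilities, optional latent
binding-mode switching) and matched screening libraries, so the entire
pipeline is testable without trajectories or a compound database.

## Worked example

```bash
hgpm simulate --n-frames 2000 --seed 7 --out models.jsonl --library-out hits.csv
hgpm build --input models.jsonl --min-count 2 --out graph.json
hgpm stats --graph graph.json
```

prints (seed 7):

```
n_models: 2000
threshold: 2
n_unique_features: 14
n_observed: 259
n_artificial: 288
n_nodes: 547
n_edges: 2143
variance_percent: 34.3
```

2,000 frames collapse to 259 distinct observed feature vectors; closing the
family under intersection adds 288 artificial nodes, and a single MDS axis
captures ~34% of the Manhattan-distance structure. Selecting the observed
supersets of the highest-frequency node and consensus-scoring them:

```bash
hgpm select --graph graph.json --anchor HF --strategy supersets --out sel.json
hgpm score --graph graph.json --hits hits.csv --selection sel.json --out summary.csv
```

```
anchor:00101111100011:supersets: 3 models, 0 hits, AUC@1%=0.00, AUC@5%=0.00,
AUC@10%=0.00, AUC@50%=0.00, AUC@100%=0.00
```

Here the HF vector is already highly specialised (8 features), its three
superset models retrieve nothing, and the truncated AUC is 0.00 across the
board — exactly the behaviour over-specific single models show in practice.
Dropping `--selection` scores the consensus over *all* observed models
(common-hits approach), which on the same data retrieves 110 hits with
AUC@100% = 0.80. `hgpm render --graph graph.json --out graph.html` writes a
self-contained interactive view: hover for feature vectors and counts, click
two nodes to highlight their intersection node.

The same API is available as a library — `hgpm.build_from_models`,
`hgpm.superset_selection`, `hgpm.truncated_roc_auc`, etc.; see
`docs/methods.md` for the underlying definitions and conventions.

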