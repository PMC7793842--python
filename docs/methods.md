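# Methods

This note documents the models, conventions and numerical choices behind
`hgpm`, in the order the pipeline applies them.

## Feature identity

A pharmacophore feature is identified by composition only: interaction type,
the set of ligand atom identifiers it involves, and the set of interacting
protein residue identifiers. 3D position, tolerance radii and direction
vectors are deliberately ignored — two H-bond acceptors through the same
ligand nitrogen count as different features if one reaches a serine and the
other a threonine. Identifier lists are sorted and deduplicated, and the
canonical serial (`TYPE|atoms|residues`, comma-joined within fields) is
injective because the separator characters are forbidden inside identifiers.
Residues use the form `RESNAME+SEQNUM` (e.g. `ARG63`), optionally suffixed
with `:CHAIN`; renumbering/alignment across systems is the caller's job.
Hydrophobic environment sets are kept verbatim: a feature over residues
{ILE211, TYR214, TYR215} is distinct from one over a superset of those
residues, even though this inflates the hydrophobic share of the catalog.
That mirrors how upstream perception tools emit hydrophobic contacts and
keeps the mapping to them faithful.

Two serial modes exist. *Ligand-aware* (default) keeps ligand atoms in the
identity and is the right choice within one protein–ligand system.
*Projected* drops the ligand part, trading ligand-side localisation for
comparability: models of different ligands against the same protein share a
feature alphabet, which is the only way a multi-system graph is meaningful.
Projection is many-to-one by construction.

## Vectors, counting, filtering

The catalog of an ensemble is the union of all observed feature keys, sorted
by serial; this fixes every feature's bit position reproducibly. Each
non-empty model becomes a bitmask; empty models are skipped but still count
toward the frame total used by fractional thresholds. Identical masks merge
into one counted vector; the appearance count is the number of MD frames
with exactly that feature set (crystal-structure reference models mark a
vector as reference but never add to the count). Filtering keeps vectors
with count ≥ t, where t is either given directly (default 2 — a vector seen
once is treated as perception noise) or as ⌊f·N⌋ for a fraction f of N
frames, floored at 2. Reference vectors are exempt from filtering so a
crystal-structure model always has a node, even when no MD frame reproduces
it.

## Graph construction

Nodes start as the filtered unique vectors. The linkage rule: if two nodes'
sets are comparable, they are connected through the subset order; if not,
their intersection is materialised — as a link to an existing equal node if
one exists, otherwise as a new *artificial* node with appearance count 0.
We run this to a **fixpoint** (intersections of intersections included), so
the node family is closed under pairwise non-empty intersection. The
fixpoint is what guarantees a *unique* graph, identical for any input
permutation; stopping after one pass would leave the result dependent on
pair-processing order. The cost is a possibly larger artificial-node count
than a single-pass construction would give. Empty intersections create
nothing — the graph keeps multiple minimal nodes rather than an artificial
universal root.

Edges are the cover relation (transitive reduction) of strict inclusion,
computed by scanning candidate subsets in decreasing popcount and keeping
the maximal ones; the reduction of a partial order is unique. Edge direction
is subset → superset, matching the left-to-right generalisation →
specialisation axis of the layout. Node identity is a content hash of the
bit pattern, stable across runs and file round-trips. In merged multi-system
graphs each node records contributing systems and per-system counts;
observed status wins over artificial when the same vector arises both ways.

## Layout

x is the feature count, so every cover edge strictly increases x. y is
classical (Torgerson) MDS of the Manhattan (= Hamming, on binary vectors)
distance matrix over *all* nodes: double-center the squared distances,
B = −½·J·D²·J, and embed along the leading eigenvector scaled by √λ₁.
Classical scaling was chosen over iterative stress majorisation because it
is exact, seedless and deterministic, and it yields a natural reliability
diagnostic: the **variance of the projection**, 100·λ₁/Σ(positive
eigenvalues). Manhattan distances need not be Euclidean-embeddable, so
negative eigenvalues can occur; they are excluded from the denominator.
Degenerate cases: a single node or an all-zero distance matrix gets
coordinate 0 and variance 100 by convention. The gauge is fixed (coordinates
centered; sign flipped so the lexicographically smallest bit pattern sits at
a non-positive coordinate) so serialized layouts are byte-stable. Node size
is an affine map of appearance count onto [6, 28] px; count 0 (artificial)
always gets the minimum, and when all counts are equal and positive they all
get the maximum. Ties in y are left untouched — no jitter is applied.

## Selection and screening

The HF node is the observed node with the highest appearance count; ties
break toward more features, then the lexicographically smallest bit string.
Superset selections (HF+, CF+) take every node whose set contains the
anchor's set, excluding artificial nodes by default since they have no model
to screen. Each selected node is screened through its representative model:
the frame with the smallest (run\_id, frame\_index) among the node's frames
— run order is lexicographic because concatenated runs carry no inherent
order. Consensus scoring is the plain common-hits count (number of selected
models retrieving a molecule), with an optional deterministic secondary sort
by best per-model fit score, then molecule id. The reported "number of
hits" of a selection is the size of the union hit list (molecules, not
conformations).

**Truncated ROC AUC.** Screening tools report early enrichment as AUC at a
percentage of the database; the exact convention is rarely published, so
ours is fully specified: molecules with consensus score > 0 are ranked by
descending score; an equal-score block is traversed as a single straight ROC
segment (trapezoid rule); unretrieved molecules are never screened, so the
curve simply ends at the last retrieved molecule; the cutoff is
⌈percent/100·N⌉ screened molecules, taking a proportional part of a block it
lands inside; the area is normalised by the FPR reached at the cutoff.
Boundary conventions: no actives retrieved within the cutoff → 0.0 (a
selection that retrieves nothing scores 0.00 at every percentage); FPR 0 at
the cutoff → 1.0. The implementation is verified against an independent
per-molecule curve-expansion oracle.

## Synthetic data

The generator emulates the statistics of MD-derived model ensembles, not
their physics. Each feature follows a two-state Markov chain with
P(on→on) = p + ρ(1−p) and P(off→on) = p(1−ρ), initialised at Bernoulli(p):
the stationary marginal is exactly the parameter p for any persistence
ρ ∈ [0, 1), and ρ is the lag-1 autocorrelation (autocorrelated frames are
what make appearance counts non-binomial in real trajectories). Optional
latent binding modes switch by a per-frame probability and override
per-feature p values, producing the multi-branch graph topology of
multi-conformation ensembles. Features are conditionally independent given
the mode — correlation enters only through mode switching. Defaults model a
kinase-like site: 14 features, ~60% hydrophobic, stationary probabilities on
a geometric ladder from 0.9 down to 0.03, persistence 0.3, two modes sharing
a 3-feature stable core with disjoint 5-feature extensions and a 1% switch
probability per frame.

The matched library draws actives that carry a designated core feature set
with probability 0.9 (independent 50% per core feature otherwise) plus 30%
random extras, and decoys as 15% sparse uniform sets; defaults are 100
actives / 400 decoys. The screening stub declares a hit iff the model's
feature set is contained in the molecule's **and** the model has ≥ 3
features — tiny models cannot be unambiguously aligned in 3D, so they
retrieve nothing; the stub reproduces that behaviour exactly.

What passing tests on synthetic data do **not** show: real feature
perception noise is not i.i.d. per frame, real actives share scaffolds
rather than feature supersets, and real screening has geometric
false-positives the containment stub cannot produce. The synthetic results
validate the machinery (counting, closure, reduction, layout, scoring), not
screening performance on any real target.

## Problem sizes and numerics

The default test and reproduction runs use 500–2,000-frame ensembles over 14
features and a 500-molecule library; the full-scale check builds a
10,000-frame ensemble (threshold ⌊0.001·N⌋ = 10) with layout and export,
which completes in a few seconds. Closure is worklist-based with integer
bitmask sets; the cover-edge scan is O(n²·deg) on typical families.
Eigendecomposition uses dense symmetric solvers; variances are clipped to
[0, 100] against rounding. All file writers sort keys, so identical graphs
serialize to identical bytes.

## Known limitations

- Feature perception is out of scope: inputs are tabular ensembles; the
  `.pml` importer is best-effort and explicitly lossy.
- The intersection fixpoint can create more artificial nodes than a
  single-pass construction; on pathological inputs (many overlapping
  mid-size sets) closure size can grow combinatorially.
- 1-D classical MDS typically captures only a modest share of the distance
  variance on real-size graphs; the variance figure should be read before
  trusting vertical proximity.
- Consensus scoring weights all selected models equally; probabilistic
  weighting schemes are intentionally not implemented.
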