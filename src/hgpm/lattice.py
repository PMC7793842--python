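"""Hierarchical graph construction: subset lattice with intersection nodes.

Observed unique feature vectors become graph nodes; whenever two nodes are
neither subset nor superset of one another, the intersection of their
feature sets is added as an *artificial* node (appearance count 0) unless an
equal node already exists.  Closure is run to a fixpoint so the resulting
node family is closed under pairwise non-empty intersection — this is what
makes the graph unique, i.e. independent of the order in which models were
encountered.  Edges are the cover relation of strict set inclusion
(subset → superset), the Hasse diagram after removing all transitively
implied paths.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .features import CountedVector, FeatureCatalog, Mode, ModeMismatchError

__all__ = [
    "Origin",
    "GraphNode",
    "HGPMGraph",
    "intersection_closure",
    "cover_edges",
    "build_graph",
    "merge_graphs",
    "meet_node",
]


class Origin:
    OBSERVED = "observed"
    ARTIFICIAL = "artificial"
    REFERENCE = "reference"


def node_id_for(mask: int) -> str:
    """Stable content hash of a bit pattern (hex mask keyed by value)."""
    return hashlib.sha1(format(mask, "x").encode()).hexdigest()[:12]


@dataclass
class GraphNode:
    """One node of the hierarchical graph.

    ``origin`` distinguishes vectors seen in the ensemble (*observed*),
    crystal-structure models (*reference*), and intersection-set vectors
    created during linkage (*artificial*, always appearance count 0).
    """

    mask: int
    feature_count: int
    appearance_count: int
    origin: str
    frames: list[tuple[str, str, int]] = field(default_factory=list)
    systems: set[str] = field(default_factory=set)
    counts_by_system: dict[str, int] = field(default_factory=dict)
    payload_refs: dict[tuple[str, str, int], str] = field(default_factory=dict)
    # layout attributes, filled by hgpm.layout.assign_layout
    x: int | None = None
    y: float | None = None
    size: float | None = None

    @property
    def node_id(self) -> str:
        return node_id_for(self.mask)


class HGPMGraph:
    """Directed acyclic graph of unique pharmacophore feature vectors.

    Nodes are keyed by bit pattern; edges point from subset to superset and
    form the cover relation (no redundant paths).  The node family is
    closed under pairwise non-empty intersection.
    """

    def __init__(
        self,
        nodes: Mapping[int, GraphNode],
        edges: set[tuple[int, int]],
        catalog: FeatureCatalog,
        metadata: dict | None = None,
    ):
        self.nodes: dict[int, GraphNode] = dict(sorted(nodes.items()))
        self.edges: set[tuple[int, int]] = set(edges)
        self.catalog = catalog
        self.metadata: dict = metadata or {}

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, mask: int) -> GraphNode:
        return self.nodes[mask]

    def observed_nodes(self) -> list[GraphNode]:
        return [n for n in self.nodes.values() if n.origin != Origin.ARTIFICIAL]

    def artificial_nodes(self) -> list[GraphNode]:
        return [n for n in self.nodes.values() if n.origin == Origin.ARTIFICIAL]

    def parents(self, mask: int) -> list[int]:
        """Direct subsets (cover predecessors) of the node."""
        return sorted(u for (u, v) in self.edges if v == mask)

    def children(self, mask: int) -> list[int]:
        """Direct supersets (cover successors) of the node."""
        return sorted(v for (u, v) in self.edges if u == mask)

    def stats(self) -> dict:
        """Composition summary: model/node counts, threshold, variance."""
        observed = [n for n in self.nodes.values() if n.origin == Origin.OBSERVED]
        artificial = self.artificial_nodes()
        reference = [n for n in self.nodes.values() if n.origin == Origin.REFERENCE]
        return {
            "n_models": self.metadata.get("n_frames"),
            "threshold": self.metadata.get("threshold"),
            "n_unique_features": len(self.catalog),
            "n_observed": len(observed),
            "n_artificial": len(artificial),
            "n_reference": len(reference),
            "n_nodes": len(self.nodes),
            "n_edges": len(self.edges),
            "variance_percent": self.metadata.get("variance_percent"),
        }


def intersection_closure(masks: Iterable[int]) -> tuple[set[int], set[int]]:
    """Close a family of non-empty sets under pairwise non-empty intersection.

    Returns ``(family, added)``: the smallest superfamily closed under
    intersection, and the subset of members that were not in the input
    (the artificial vectors).  Runs to a fixpoint, so intersections of
    intersections are included; this is what makes the result independent
    of pair-processing order.
    """
    family = set(masks)
    if not family:
        raise ValueError("intersection closure of an empty family")
    if 0 in family:
        raise ValueError("the empty feature set cannot be a node")
    added: set[int] = set()
    worklist = list(family)
    while worklist:
        s = worklist.pop()
        new: list[int] = []
        for t in family:
            i = s & t
            if i and i not in family and i not in added:
                added.add(i)
                new.append(i)
        family.update(new)
        worklist.extend(new)
    return family, added


def cover_edges(family: Iterable[int]) -> set[tuple[int, int]]:
    """Cover relation (Hasse diagram) of strict subset order on *family*.

    An edge (u, v) survives iff u ⊂ v with no w in the family strictly
    between them — the transitive reduction, unique for a partial order.
    """
    members = sorted(set(family), key=lambda m: (m.bit_count(), m))
    edges: set[tuple[int, int]] = set()
    for i, v in enumerate(members):
        # candidate parents: strict subsets of v, widest first
        subs = [u for u in members[:i] if u & v == u and u != v]
        subs.sort(key=lambda m: -m.bit_count())
        maximal: list[int] = []
        for u in subs:
            if not any(u & p == u for p in maximal):
                maximal.append(u)
                edges.add((u, v))
    return edges


def build_graph(
    counted: Sequence[CountedVector],
    catalog: FeatureCatalog,
    metadata: dict | None = None,
) -> HGPMGraph:
    """Assemble the hierarchical graph from filtered counted vectors.

    Observed/reference appearance counts carry over; intersection nodes get
    count 0.  Node and edge sets depend only on the set of input vectors,
    not their order.
    """
    if not counted:
        raise ValueError("cannot build a graph from no vectors")
    nodes: dict[int, GraphNode] = {}
    n_bits = len(catalog)
    for cv in counted:
        if cv.mask <= 0:
            raise ValueError("empty feature vectors cannot become nodes")
        if cv.mask >> n_bits:
            raise ValueError("vector has bits outside the catalog")
        if cv.mask in nodes:
            raise ValueError(
                f"duplicate bit pattern {catalog.bits_string(cv.mask)}; "
                "run count_unique first"
            )
        origin = Origin.OBSERVED if cv.observed else Origin.REFERENCE
        systems = {p[0] for p in cv.frames}
        counts_by_system: dict[str, int] = {}
        for p in cv.frames:
            counts_by_system[p[0]] = counts_by_system.get(p[0], 0) + 1
        nodes[cv.mask] = GraphNode(
            mask=cv.mask,
            feature_count=cv.mask.bit_count(),
            appearance_count=cv.appearance_count,
            origin=origin,
            frames=list(cv.frames),
            systems=systems,
            counts_by_system=counts_by_system,
            payload_refs=dict(cv.payload_refs),
        )
    family, added = intersection_closure(nodes.keys())
    for mask in added:
        nodes[mask] = GraphNode(
            mask=mask,
            feature_count=mask.bit_count(),
            appearance_count=0,
            origin=Origin.ARTIFICIAL,
        )
    edges = cover_edges(family)
    meta = dict(metadata or {})
    meta.setdefault("mode", catalog.mode)
    return HGPMGraph(nodes, edges, catalog, meta)


def merge_graphs(
    counted_by_system: Mapping[str, Sequence[CountedVector]],
    catalog: FeatureCatalog,
    metadata: dict | None = None,
) -> HGPMGraph:
    """Build one graph from several systems' vectors over a shared catalog.

    Requires projected-mode serials: with ligand atoms in the identity,
    features of different ligands can never coincide, so a multi-system
    graph is only meaningful after projection onto the protein.  Vectors
    equal across systems merge into one node whose ``systems`` set and
    per-system appearance counts record every contributor.
    """
    if catalog.mode != Mode.PROJECTED:
        raise ModeMismatchError(
            "multi-system graphs require projected-mode feature serials"
        )
    merged: dict[int, CountedVector] = {}
    for system_id in sorted(counted_by_system):
        for cv in counted_by_system[system_id]:
            tgt = merged.get(cv.mask)
            if tgt is None:
                tgt = merged[cv.mask] = CountedVector(
                    cv.mask, 0, [], observed=False, reference=False
                )
            tgt.appearance_count += cv.appearance_count
            tgt.frames.extend(cv.frames)
            tgt.observed = tgt.observed or cv.observed
            tgt.reference = tgt.reference or cv.reference
            tgt.payload_refs.update(cv.payload_refs)
    for cv in merged.values():
        cv.frames.sort(key=lambda p: (p[1], p[2]))
    meta = dict(metadata or {})
    meta["systems"] = sorted(counted_by_system)
    return build_graph(sorted(merged.values(), key=lambda c: c.mask), catalog, meta)


def meet_node(graph: HGPMGraph, node_a: GraphNode, node_b: GraphNode) -> GraphNode | None:
    """The node holding set(a) ∩ set(b); ``None`` iff the intersection is empty.

    Closure guarantees the meet exists whenever the intersection is
    non-empty, which is what lets an interactive view highlight the common
    feature set of any two selected nodes.
    """
    for n in (node_a, node_b):
        if n.mask not in graph.nodes:
            raise KeyError(f"node {n.node_id} is not in the graph")
    meet = node_a.mask & node_b.mask
    if meet == 0:
        return None
    return graph.nodes[meet]
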