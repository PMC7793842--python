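"""Deterministic 2-D layout: feature-count columns × 1-D classical MDS.

x places each node in the column of its feature count, so specificity grows
left to right and every cover edge points rightwards.  y comes from
classical (Torgerson) multidimensional scaling of the pairwise Manhattan
distances between feature vectors, collapsed to one axis; the proportion of
distance variance captured by that single axis is reported as a reliability
diagnostic.  Classical MDS is seedless and exact, so the layout is a pure
function of the graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .lattice import HGPMGraph

__all__ = [
    "LayoutResult",
    "manhattan_matrix",
    "mds_1d",
    "node_sizes",
    "assign_layout",
]

SIZE_MIN = 6.0
SIZE_MAX = 28.0


@dataclass
class LayoutResult:
    masks: list[int]
    x: list[int]
    y: list[float]
    size: list[float]
    variance_percent: float


def manhattan_matrix(vectors: np.ndarray) -> np.ndarray:
    """Pairwise Manhattan distances between binary feature vectors.

    On 0/1 vectors the Manhattan distance equals the Hamming distance
    (number of differing features).
    """
    arr = np.asarray(vectors, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D array of feature vectors")
    if arr.shape[0] == 1:
        return np.zeros((1, 1))
    return squareform(pdist(arr, metric="cityblock"))


def mds_1d(distances: np.ndarray, sign_keys: list | None = None) -> tuple[np.ndarray, float]:
    """Classical (Torgerson) scaling to one dimension.

    Double-centers the squared-distance matrix B = -1/2 J D² J and embeds
    along the leading eigenvector scaled by √λ₁.  Returns centered
    coordinates and the proportion of variance captured,
    100·λ₁ / Σ(positive eigenvalues).  Manhattan distances need not be
    Euclidean-embeddable; negative eigenvalues are excluded from the
    denominator.

    The gauge is fixed for byte-stable output: coordinates are centered
    and the sign is flipped so the element with the smallest ``sign_keys``
    entry (input index by default) gets a non-positive coordinate.
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    if n == 1:
        return np.zeros(1), 100.0
    if not D.any():
        return np.zeros(n), 100.0
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2.0  # guard against accumulated asymmetry
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    lam1 = eigvals[0]
    positive = eigvals[eigvals > 1e-12]
    variance = 100.0 * lam1 / positive.sum() if positive.size else 100.0
    variance = float(min(100.0, max(0.0, variance)))
    coords = eigvecs[:, 0] * np.sqrt(max(lam1, 0.0))
    coords = coords - coords.mean()
    anchor = 0 if sign_keys is None else min(range(n), key=lambda i: sign_keys[i])
    if coords[anchor] > 0:
        coords = -coords
    return coords, variance


def node_sizes(
    counts: list[int], size_min: float = SIZE_MIN, size_max: float = SIZE_MAX
) -> list[float]:
    """Map appearance counts affinely onto [size_min, size_max].

    Count 0 (artificial nodes) always maps to ``size_min``.  When all
    non-zero counts are equal, they all get ``size_max``.
    """
    if size_min >= size_max:
        raise ValueError("size_min must be < size_max")
    if not counts:
        return []
    lo, hi = min(counts), max(counts)
    if lo == hi:
        return [size_min if c == 0 else size_max for c in counts]
    span = size_max - size_min
    return [size_min + (c - lo) / (hi - lo) * span for c in counts]


def assign_layout(
    graph: HGPMGraph,
    size_min: float = SIZE_MIN,
    size_max: float = SIZE_MAX,
    jitter_seed: int | None = None,
) -> LayoutResult:
    """Compute and attach (x, y, size) to every node of *graph*.

    All nodes — observed, reference and artificial — enter the MDS
    together, so vertical proximity reflects feature-set similarity across
    the whole graph.  The variance of the projection is stored in the graph
    metadata.  No jitter is applied by default; ``jitter_seed`` adds a
    small seeded vertical perturbation (±2% of the y range) to separate
    coincident nodes in dense graphs.
    """
    masks = sorted(graph.nodes)
    n_bits = len(graph.catalog)
    vecs = np.zeros((len(masks), n_bits))
    for i, m in enumerate(masks):
        for b in range(n_bits):
            if m >> b & 1:
                vecs[i, b] = 1.0
    D = manhattan_matrix(vecs) if len(masks) > 1 else np.zeros((1, 1))
    bit_strings = [graph.catalog.bits_string(m) for m in masks]
    y, variance = mds_1d(D, sign_keys=bit_strings)
    if jitter_seed is not None:
        rng = np.random.default_rng(jitter_seed)
        span = (y.max() - y.min()) or 1.0
        y = y + rng.uniform(-0.02, 0.02, size=y.shape) * span
    counts = [graph.nodes[m].appearance_count for m in masks]
    sizes = node_sizes(counts, size_min, size_max)
    xs = [graph.nodes[m].feature_count for m in masks]
    for i, m in enumerate(masks):
        node = graph.nodes[m]
        node.x = xs[i]
        node.y = float(y[i])
        node.size = sizes[i]
    graph.metadata["variance_percent"] = variance
    return LayoutResult(masks, xs, [float(v) for v in y], sizes, variance)
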