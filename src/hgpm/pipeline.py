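"""High-level convenience pipeline: models → filtered vectors → graph."""

from __future__ import annotations

import logging
from typing import Sequence

from .features import (
    PharmacophoreModel,
    build_catalog,
    count_unique,
    filter_by_count,
    vectorize,
)
from .lattice import HGPMGraph, build_graph
from .layout import assign_layout

log = logging.getLogger("hgpm")


def build_from_models(
    models: Sequence[PharmacophoreModel],
    min_count: int | None = 2,
    fraction: float | None = None,
    layout: bool = True,
    metadata: dict | None = None,
) -> HGPMGraph:
    """Run the full graph-construction pipeline on an ensemble.

    Counts every frame (including empty ones) toward ``n_frames`` used for
    fractional thresholds; reference models bypass the count filter.
    """
    if fraction is not None:
        min_count = None
    n_frames = sum(1 for m in models if not m.is_reference)
    catalog = build_catalog(models)
    vectors, skipped = vectorize(models, catalog)
    if skipped:
        log.info("skipped %d empty models (of %d frames)", len(skipped), n_frames)
    counted = count_unique(vectors)
    kept, threshold = filter_by_count(
        counted, min_count=min_count, fraction=fraction, n_frames=n_frames
    )
    log.info(
        "%d frames -> %d unique vectors -> %d kept at threshold %d",
        n_frames, len(counted), len(kept), threshold,
    )
    meta = {
        "n_frames": n_frames,
        "n_skipped_empty": len(skipped),
        "threshold": threshold,
        "systems": sorted({m.system_id for m in models}),
    }
    meta.update(metadata or {})
    graph = build_graph(kept, catalog, meta)
    log.info(
        "graph: %d observed + %d artificial nodes, %d edges",
        len(graph.observed_nodes()), len(graph.artificial_nodes()), len(graph.edges),
    )
    if layout:
        assign_layout(graph)
    return graph
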