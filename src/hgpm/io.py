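"""File formats: model-set files, graph persistence, interactive HTML.

Canonical interchange for ensembles is JSON Lines — one header line, then
one model per line — which streams well for 10,000-frame trajectories.  A
CSV layout (one row per feature) serves spreadsheet users, and a
best-effort reader for LigandScout-style pharmacophore XML (.pml) extracts
what it can.  Graphs persist canonically as JSON (bit patterns stored as
hex against the catalog, bit-exact round-trip) and export to GraphML for
standard graph tooling.  All writers emit keys in a fixed order so repeated
runs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import pandas as pd
from lxml import etree

from . import __version__
from .features import (
    CountedVector,
    FeatureCatalog,
    FeatureKey,
    Mode,
    PharmacophoreModel,
    VocabularyError,
    make_feature_key,
    parse_feature_key,
)
from .lattice import GraphNode, HGPMGraph
from .selection import GRAY, color_by_metric

log = logging.getLogger("hgpm")

__all__ = [
    "ParseError",
    "read_model_set",
    "write_model_set",
    "write_graph",
    "read_graph",
    "write_graphml",
    "render_html",
    "read_config",
]


class ParseError(ValueError):
    """Malformed record, annotated with file location."""


# ---------------------------------------------------------------- model sets

def _model_to_record(m: PharmacophoreModel) -> dict:
    rec = {
        "frame_index": m.frame_index,
        "is_reference": m.is_reference,
        "features": [
            {
                "type": k.feature_type,
                "ligand_atoms": list(k.ligand_part),
                "residues": list(k.environment),
            }
            for k in sorted(m.features, key=lambda k: k.serial)
        ],
    }
    if m.payload_ref is not None:
        rec["payload_ref"] = m.payload_ref
    return rec


def _record_to_model(rec: dict, header: dict, where: str) -> PharmacophoreModel:
    try:
        feats = frozenset(
            make_feature_key(
                f["type"], f.get("ligand_atoms", []), f["residues"], header["mode"]
            )
            for f in rec["features"]
        )
        return PharmacophoreModel(
            system_id=rec.get("system_id", header["system_id"]),
            run_id=rec.get("run_id", header["run_id"]),
            frame_index=int(rec["frame_index"]),
            features=feats,
            payload_ref=rec.get("payload_ref"),
            is_reference=bool(rec.get("is_reference", False)),
        )
    except VocabularyError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"{where}: malformed model record ({exc})") from exc


def write_model_set(models: list[PharmacophoreModel], path, format: str = "jsonl",
                    header_extra: dict | None = None) -> None:
    """Write an ensemble; frame indexing is 0-based (stated in the header)."""
    path = Path(path)
    if not models:
        raise ValueError("refusing to write an empty model set")
    modes = {k.mode for m in models for k in m.features} or {Mode.LIGAND_AWARE}
    if len(modes) > 1:
        raise ValueError("model set mixes feature modes")
    header = {
        "hgpm_model_set": 1,
        "mode": modes.pop(),
        "system_id": models[0].system_id,
        "run_id": models[0].run_id,
        "n_frames": len(models),
        "frame_indexing": "0-based",
    }
    header.update(header_extra or {})
    if format == "jsonl":
        with path.open("w") as fh:
            fh.write(json.dumps(header, sort_keys=True) + "\n")
            for m in models:
                rec = _model_to_record(m)
                if (m.system_id, m.run_id) != (header["system_id"], header["run_id"]):
                    rec["system_id"], rec["run_id"] = m.system_id, m.run_id
                fh.write(json.dumps(rec, sort_keys=True) + "\n")
    elif format == "csv":
        rows = []
        for m in models:
            if not m.features:
                rows.append({"system_id": m.system_id, "run_id": m.run_id,
                             "frame_index": m.frame_index,
                             "is_reference": int(m.is_reference),
                             "feature_type": "", "ligand_atoms": "", "residues": ""})
            for k in sorted(m.features, key=lambda k: k.serial):
                rows.append({
                    "system_id": m.system_id, "run_id": m.run_id,
                    "frame_index": m.frame_index, "is_reference": int(m.is_reference),
                    "feature_type": k.feature_type,
                    "ligand_atoms": ";".join(k.ligand_part),
                    "residues": ";".join(k.environment),
                })
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown model-set format {format!r}")


def read_model_set(path, format: str | None = None) -> list[PharmacophoreModel]:
    """Read an ensemble file (jsonl, csv or pml; inferred from the suffix)."""
    path = Path(path)
    if format is None:
        format = {".jsonl": "jsonl", ".csv": "csv", ".pml": "pml"}.get(
            path.suffix, "jsonl"
        )
    if format == "jsonl":
        return _read_jsonl(path)
    if format == "csv":
        return _read_csv(path)
    if format == "pml":
        return read_pml(path)
    raise ValueError(f"unknown model-set format {format!r}")


def _read_jsonl(path: Path) -> list[PharmacophoreModel]:
    models = []
    with path.open() as fh:
        try:
            header = json.loads(fh.readline())
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}:1: bad header ({exc})") from exc
        if "mode" not in header:
            raise ParseError(f"{path}:1: header lacks 'mode'")
        header.setdefault("system_id", "unknown")
        header.setdefault("run_id", "run1")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}:{lineno}: bad JSON ({exc})") from exc
            models.append(_record_to_model(rec, header, f"{path}:{lineno}"))
    log.info("read %d models from %s", len(models), path)
    return models


def _read_csv(path: Path) -> list[PharmacophoreModel]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    needed = {"system_id", "run_id", "frame_index", "feature_type", "residues"}
    missing = needed - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    grouped: dict[tuple[str, str, int, bool], set[FeatureKey]] = {}
    for i, row in df.iterrows():
        where = f"{path}: row {i + 2}"
        try:
            key = (row["system_id"], row["run_id"], int(row["frame_index"]),
                   bool(int(row.get("is_reference", "0") or 0)))
        except ValueError as exc:
            raise ParseError(f"{where}: bad frame index ({exc})") from exc
        feats = grouped.setdefault(key, set())
        if row["feature_type"]:
            atoms = [a for a in row.get("ligand_atoms", "").split(";") if a]
            residues = [r for r in row["residues"].split(";") if r]
            mode = Mode.LIGAND_AWARE if atoms else Mode.PROJECTED
            try:
                feats.add(make_feature_key(row["feature_type"], atoms, residues, mode))
            except VocabularyError as exc:
                raise VocabularyError(f"{where}: {exc}") from exc
    models = [
        PharmacophoreModel(s, r, f, frozenset(feats), is_reference=ref)
        for (s, r, f, ref), feats in sorted(grouped.items())
    ]
    log.info("read %d models from %s", len(models), path)
    return models


#: Map from LigandScout pharmacophore XML feature names to our type codes.
_PML_TYPES = {
    "H": "H", "HY": "H", "AR": "AR", "HBA": "HBA", "HBD": "HBD",
    "PI": "PI", "NI": "NI", "XBD": "XBD",
}


def read_pml(path) -> list[PharmacophoreModel]:
    """Best-effort LigandScout pharmacophore XML import (explicitly lossy).

    Only the feature type (``name`` attribute) and any ligand/target
    annotations are extracted; geometry, tolerances and weights are
    ignored.  Elements that cannot be mapped are logged and skipped.
    """
    path = Path(path)
    tree = etree.parse(str(path))
    models = []
    pharmacophores = tree.findall(".//pharmacophore")
    if not pharmacophores and tree.getroot().tag == "pharmacophore":
        pharmacophores = [tree.getroot()]
    for idx, ph in enumerate(pharmacophores):
        feats = set()
        for el in ph:
            name = el.get("name", "")
            ftype = _PML_TYPES.get(name.upper())
            if ftype is None:
                log.warning("%s: skipping unmapped feature element %r", path, name)
                continue
            atoms = [a for a in (el.get("ligand") or "").split(";") if a]
            residues = [r for r in (el.get("target") or "").split(";") if r]
            if not residues:
                log.warning("%s: feature %r lacks target residues; skipped", path, name)
                continue
            mode = Mode.LIGAND_AWARE if atoms else Mode.PROJECTED
            feats.add(make_feature_key(ftype, atoms, residues, mode))
        models.append(
            PharmacophoreModel(
                system_id=ph.get("system", path.stem),
                run_id=ph.get("run", "pml"),
                frame_index=int(ph.get("frame", idx)),
                features=frozenset(feats),
                is_reference=ph.get("reference", "false").lower() == "true",
            )
        )
    log.info("read %d pharmacophores from %s (lossy import)", len(models), path)
    return models


# -------------------------------------------------------------------- graphs

def _node_to_json(n: GraphNode, catalog: FeatureCatalog) -> dict:
    return {
        "bits": format(n.mask, "x"),
        "origin": n.origin,
        "appearance_count": n.appearance_count,
        "frames": [list(p) for p in n.frames],
        "systems": sorted(n.systems),
        "counts_by_system": dict(sorted(n.counts_by_system.items())),
        "payload_refs": {"|".join(map(str, k)): v
                         for k, v in sorted(n.payload_refs.items())},
        "x": n.x,
        "y": n.y,
        "size": n.size,
    }


def write_graph(graph: HGPMGraph, path, format: str = "json") -> None:
    path = Path(path)
    if format == "json":
        doc = {
            "hgpm_graph": 1,
            "tool_version": __version__,
            "metadata": {k: graph.metadata[k] for k in sorted(graph.metadata)},
            "mode": graph.catalog.mode,
            "catalog": [k.serial for k in graph.catalog],
            "nodes": [_node_to_json(graph.nodes[m], graph.catalog)
                      for m in sorted(graph.nodes)],
            "edges": [[format_mask(u), format_mask(v)]
                      for (u, v) in sorted(graph.edges)],
        }
        path.write_text(json.dumps(doc, sort_keys=True, indent=1) + "\n")
    elif format == "graphml":
        write_graphml(graph, path)
    else:
        raise ValueError(f"unknown graph format {format!r}")


def format_mask(mask: int) -> str:
    return format(mask, "x")


def read_graph(path) -> HGPMGraph:
    path = Path(path)
    doc = json.loads(path.read_text())
    if doc.get("hgpm_graph") != 1:
        raise ParseError(f"{path}: not an hgpm graph file")
    mode = doc["mode"]
    catalog = FeatureCatalog(
        (parse_feature_key(s, mode) for s in doc["catalog"]), mode=mode
    )
    nodes: dict[int, GraphNode] = {}
    for rec in doc["nodes"]:
        mask = int(rec["bits"], 16)
        payloads = {}
        for k, v in rec.get("payload_refs", {}).items():
            s, r, f = k.rsplit("|", 2)
            payloads[(s, r, int(f))] = v
        nodes[mask] = GraphNode(
            mask=mask,
            feature_count=mask.bit_count(),
            appearance_count=rec["appearance_count"],
            origin=rec["origin"],
            frames=[tuple(p) for p in rec["frames"]],
            systems=set(rec["systems"]),
            counts_by_system=dict(rec.get("counts_by_system", {})),
            payload_refs=payloads,
            x=rec.get("x"),
            y=rec.get("y"),
            size=rec.get("size"),
        )
    edges = {(int(u, 16), int(v, 16)) for u, v in doc["edges"]}
    return HGPMGraph(nodes, edges, catalog, dict(doc.get("metadata", {})))


def write_graphml(graph: HGPMGraph, path) -> None:
    """GraphML export with node attributes usable by standard graph tools."""
    g = nx.DiGraph()
    for mask in sorted(graph.nodes):
        n = graph.nodes[mask]
        g.add_node(
            n.node_id,
            bits=graph.catalog.bits_string(mask),
            origin=n.origin,
            count=n.appearance_count,
            column=n.feature_count,
            y=-1.0 if n.y is None else float(n.y),
            size=-1.0 if n.size is None else float(n.size),
            systems=";".join(sorted(n.systems)),
        )
    for (u, v) in sorted(graph.edges):
        g.add_edge(graph.nodes[u].node_id, graph.nodes[v].node_id)
    nx.write_graphml(g, path)


# ------------------------------------------------------------------ rendering

#: Feature-type colors for the feature-vector strip.
TYPE_COLORS = {
    "H": "#f4c60f", "HBA": "#d32f2f", "HBD": "#388e3c", "AR": "#1565c0",
    "PI": "#6a1b9a", "NI": "#4e342e", "XBD": "#9e9e9e",
}
OBSERVED_COLOR = "#1f77b4"
ARTIFICIAL_COLOR = "#ff7f0e"
REFERENCE_COLOR = "#2ca02c"

_HTML_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>HGPM graph</title>
<style>
 body {{ font-family: sans-serif; margin: 12px; }}
 .node {{ stroke: #333; stroke-width: 1; cursor: pointer; }}
 .node.selected {{ stroke: #000; stroke-width: 3; }}
 .node.meet {{ stroke: #e91e63; stroke-width: 4; }}
 .edge {{ stroke: #bbb; stroke-width: 1; fill: none; }}
 #tip {{ position: absolute; background: #fffbe6; border: 1px solid #999;
        padding: 4px 6px; font-size: 12px; display: none; pointer-events: none; }}
</style></head>
<body>
<h3>Hierarchical graph of pharmacophore models</h3>
<p>{n_nodes} nodes ({n_observed} observed, {n_artificial} artificial),
{n_edges} edges; MDS projection variance {variance:.1f}%.
Click two nodes to highlight their common-feature (intersection) node.</p>
<div id="tip"></div>
<svg id="g" width="{width}" height="{height}">{strip}{edges}{nodes}</svg>
<script>
const NODES = {nodes_json};
const BY_BITS = Object.fromEntries(NODES.map(n => [n.bits, n.id]));
let selected = [];
function bitsAnd(a, b) {{
  let out = "";
  for (let i = 0; i < a.length; i++) out += (a[i] === "1" && b[i] === "1") ? "1" : "0";
  return out;
}}
function clearClass(cls) {{
  document.querySelectorAll("." + cls).forEach(e => e.classList.remove(cls));
}}
document.querySelectorAll(".node").forEach(el => {{
  el.addEventListener("mousemove", ev => {{
    const n = NODES[el.dataset.idx];
    const tip = document.getElementById("tip");
    tip.style.display = "block";
    tip.style.left = (ev.pageX + 12) + "px";
    tip.style.top = (ev.pageY + 12) + "px";
    tip.innerHTML = "<b>" + n.origin + "</b> count=" + n.count +
      " features=" + n.column + "<br><code>" + n.bits + "</code>" +
      (n.label ? "<br>" + n.label : "");
  }});
  el.addEventListener("mouseleave", () => {{
    document.getElementById("tip").style.display = "none";
  }});
  el.addEventListener("click", () => {{
    if (selected.length === 2) {{ clearClass("selected"); clearClass("meet"); selected = []; }}
    el.classList.add("selected");
    selected.push(el);
    if (selected.length === 2) {{
      const a = NODES[selected[0].dataset.idx].bits;
      const b = NODES[selected[1].dataset.idx].bits;
      const meet = BY_BITS[bitsAnd(a, b)];
      if (meet !== undefined) {{
        const m = document.getElementById("n" + meet);
        if (m) m.classList.add("meet");
      }}
    }}
  }});
}});
</script>
</body></html>
"""


def render_html(
    graph: HGPMGraph,
    path,
    color_metric: dict[int, float] | None = None,
    label_nodes: dict[int, str] | None = None,
    width: int = 1100,
    height: int = 650,
) -> None:
    """Write a self-contained interactive HTML view of the graph.

    Hovering a node shows its feature vector and appearance count; clicking
    two nodes highlights the node holding their feature-set intersection.
    Default coloring is blue observed / orange artificial / green
    reference; with ``color_metric`` (e.g. per-node AUC in [0, 1]) observed
    nodes get a red→green scale and artificial nodes turn gray.
    """
    masks = sorted(graph.nodes)
    if any(graph.nodes[m].x is None or graph.nodes[m].y is None for m in masks):
        raise ValueError("graph has no layout; run assign_layout first")
    if color_metric is not None:
        colors = color_by_metric(graph, color_metric)
    else:
        colors = {}
        for m in masks:
            origin = graph.nodes[m].origin
            colors[m] = {"observed": OBSERVED_COLOR, "artificial": ARTIFICIAL_COLOR,
                         "reference": REFERENCE_COLOR}.get(origin, GRAY)

    strip_h = 26
    xs = [graph.nodes[m].x for m in masks]
    ys = [graph.nodes[m].y for m in masks]
    x_lo, x_hi = min(xs), max(xs)
    y_lo, y_hi = min(ys), max(ys)
    pad = 45

    def sx(x):
        span = (x_hi - x_lo) or 1
        return pad + (x - x_lo) / span * (width - 2 * pad)

    def sy(y):
        span = (y_hi - y_lo) or 1
        return strip_h + pad + (y - y_lo) / span * (height - strip_h - 2 * pad)

    # feature-vector strip across the top, one box per catalog entry
    n_feat = max(len(graph.catalog), 1)
    bw = (width - 2 * pad) / n_feat
    strip = []
    for i, key in enumerate(graph.catalog):
        color = TYPE_COLORS.get(key.feature_type, GRAY)
        strip.append(
            f'<rect x="{pad + i * bw:.1f}" y="2" width="{max(bw - 1, 1):.1f}" '
            f'height="{strip_h - 6}" fill="{color}"><title>{key.serial}</title></rect>'
        )
    edges_svg = []
    for (u, v) in sorted(graph.edges):
        nu, nv = graph.nodes[u], graph.nodes[v]
        edges_svg.append(
            f'<line class="edge" x1="{sx(nu.x):.1f}" y1="{sy(nu.y):.1f}" '
            f'x2="{sx(nv.x):.1f}" y2="{sy(nv.y):.1f}"/>'
        )
    nodes_svg, nodes_json = [], []
    for idx, m in enumerate(masks):
        n = graph.nodes[m]
        nodes_svg.append(
            f'<circle class="node" id="n{idx}" data-idx="{idx}" '
            f'cx="{sx(n.x):.1f}" cy="{sy(n.y):.1f}" r="{(n.size or 8) / 2:.1f}" '
            f'fill="{colors[m]}"/>'
        )
        nodes_json.append({
            "id": idx,
            "bits": graph.catalog.bits_string(m),
            "origin": n.origin,
            "count": n.appearance_count,
            "column": n.feature_count,
            "label": (label_nodes or {}).get(m, ""),
        })
    html = _HTML_TEMPLATE.format(
        n_nodes=len(graph.nodes),
        n_observed=len(graph.observed_nodes()),
        n_artificial=len(graph.artificial_nodes()),
        n_edges=len(graph.edges),
        variance=graph.metadata.get("variance_percent", float("nan")),
        width=width,
        height=height,
        strip="".join(strip),
        edges="".join(edges_svg),
        nodes="".join(nodes_svg),
        nodes_json=json.dumps(nodes_json),
    )
    Path(path).write_text(html)
    log.info("wrote interactive view with %d nodes to %s", len(graph.nodes), path)


# -------------------------------------------------------------------- config

def read_config(path) -> dict[str, str]:
    """Plain-text key=value configuration ('#' starts a comment)."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParseError(f"{path}:{lineno}: expected key=value, got {line!r}")
        key, val = line.split("=", 1)
        out[key.strip()] = val.strip()
    return out
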