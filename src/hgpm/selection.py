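"""Graph-driven model selection and consensus virtual-screening metrics.

A graph node stands for a set of identically-composed pharmacophore models;
screening selections are phrased on the graph: the highest-frequency (HF)
node, the node of a crystal-structure (PDB) model, a common-features (CF)
node, or every observed superset of such an anchor (HF+, CF+ …).  Each
selected node is screened through its representative model — the first
model observed in the trajectory with that exact feature vector — and hits
are combined by the common-hits consensus count.  Early enrichment is
measured by the ROC AUC truncated at a percentage of the screened database.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .features import FeatureKey
from .lattice import GraphNode, HGPMGraph, Origin

__all__ = [
    "HitTable",
    "ScreeningSummary",
    "find_node",
    "highest_frequency_node",
    "superset_selection",
    "representative_models",
    "consensus_score",
    "truncated_roc_auc",
    "screening_summary",
    "color_by_metric",
]

ACTIVE = "active"
DECOY = "decoy"


class HitTable:
    """Molecules × models hit indicators with active/decoy labels.

    ``hits`` maps (molecule_id, model_id) to True (the model retrieved the
    molecule); absent pairs are misses.  ``fit_scores`` optionally carries a
    per-hit geometric fit score used only as a deterministic secondary sort.
    """

    def __init__(
        self,
        labels: Mapping[str, str],
        model_ids: Iterable[str],
        hits: Mapping[tuple[str, str], bool] | None = None,
        fit_scores: Mapping[tuple[str, str], float] | None = None,
    ):
        bad = {v for v in labels.values()} - {ACTIVE, DECOY}
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}")
        self.labels = dict(labels)
        self.model_ids = sorted(set(model_ids))
        self.hits: dict[tuple[str, str], bool] = {}
        self.fit_scores = dict(fit_scores or {})
        for (mol, model), flag in (hits or {}).items():
            if mol not in self.labels:
                raise KeyError(f"unknown molecule {mol!r}")
            if model not in self.model_ids:
                raise KeyError(f"unknown model {model!r}")
            if flag:
                self.hits[(mol, model)] = True

    @property
    def molecule_ids(self) -> list[str]:
        return sorted(self.labels)

    @property
    def n_molecules(self) -> int:
        return len(self.labels)

    def n_actives(self) -> int:
        return sum(1 for v in self.labels.values() if v == ACTIVE)

    def add_hit(self, molecule_id: str, model_id: str, fit_score: float | None = None):
        if molecule_id not in self.labels:
            raise KeyError(f"unknown molecule {molecule_id!r}")
        if model_id not in self.model_ids:
            raise KeyError(f"unknown model {model_id!r}")
        self.hits[(molecule_id, model_id)] = True
        if fit_score is not None:
            self.fit_scores[(molecule_id, model_id)] = fit_score

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "molecule_id": mol,
                "label": self.labels[mol],
                "model_id": model,
                "hit": 1,
                "fit_score": self.fit_scores.get((mol, model), ""),
            }
            for (mol, model) in sorted(self.hits)
        ]
        hit_mols = {m for (m, _) in self.hits}
        for mol in self.molecule_ids:  # keep label rows for never-hit molecules
            if mol not in hit_mols:
                rows.append(
                    {
                        "molecule_id": mol,
                        "label": self.labels[mol],
                        "model_id": "",
                        "hit": 0,
                        "fit_score": "",
                    }
                )
        hit_models = {m for (_, m) in self.hits}
        for model in self.model_ids:  # register models that retrieved nothing
            if model not in hit_models:
                rows.append(
                    {
                        "molecule_id": "",
                        "label": "",
                        "model_id": model,
                        "hit": 0,
                        "fit_score": "",
                    }
                )
        return pd.DataFrame(
            rows, columns=["molecule_id", "label", "model_id", "hit", "fit_score"]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "HitTable":
        df = pd.read_csv(
            path, dtype={"molecule_id": str, "model_id": str}, keep_default_na=False
        )
        labels = {m: l for m, l in zip(df["molecule_id"], df["label"]) if m}
        models = sorted({m for m in df["model_id"] if m})
        table = cls(labels, models)
        for _, row in df.iterrows():
            if int(row.get("hit", 0) or 0) == 1 and row["model_id"] and row["molecule_id"]:
                fs = row.get("fit_score")
                fs = float(fs) if fs not in ("", None) and not pd.isna(fs) else None
                table.add_hit(row["molecule_id"], row["model_id"], fs)
        return table


@dataclass
class ScreeningSummary:
    """One consensus-screening run: selection, hit count and truncated AUCs."""

    selection_id: str
    n_common_features: int
    n_models: int
    n_hits: int
    auc_at: dict[float, float] = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {
            "selection": self.selection_id,
            "n_common_features": self.n_common_features,
            "n_models": self.n_models,
            "n_hits": self.n_hits,
        }
        for pct in sorted(self.auc_at):
            row[f"auc_at_{pct:g}%"] = round(self.auc_at[pct], 2)
        return row


def find_node(graph: HGPMGraph, query: Iterable[FeatureKey]) -> GraphNode | None:
    """Exact-match lookup of a feature set in the graph (or ``None``)."""
    keys = list(query)
    modes = {k.mode for k in keys}
    if modes and modes != {graph.catalog.mode}:
        raise ValueError(
            f"query mode {sorted(modes)} does not match graph mode {graph.catalog.mode!r}"
        )
    mask = 0
    for k in keys:
        if k not in graph.catalog:
            return None  # a feature never observed cannot be in any node
        mask |= 1 << graph.catalog.index(k)
    return graph.nodes.get(mask)


def highest_frequency_node(graph: HGPMGraph) -> GraphNode:
    """The observed node with the highest appearance count (the HF node).

    Ties break toward the larger feature count, then the lexicographically
    smallest bit string — documented, deterministic.
    """
    observed = [n for n in graph.nodes.values() if n.origin == Origin.OBSERVED]
    if not observed:
        raise ValueError("graph has no observed nodes")
    return max(
        observed,
        key=lambda n: (
            n.appearance_count,
            n.feature_count,
            [-ord(c) for c in graph.catalog.bits_string(n.mask)],
        ),
    )


def superset_selection(
    graph: HGPMGraph, anchor: GraphNode, observed_only: bool = True
) -> list[GraphNode]:
    """All nodes whose feature set contains the anchor's set (HF+/CF+ style).

    Artificial nodes are excluded by default: they have no model behind
    them, so they cannot be screened.  The anchor itself is included when
    it qualifies.  Result sorted by (feature_count, bit pattern).
    """
    if anchor.mask not in graph.nodes:
        raise KeyError(f"anchor {anchor.node_id} is not in the graph")
    out = []
    for n in graph.nodes.values():
        if anchor.mask & n.mask != anchor.mask:
            continue
        if observed_only and n.origin == Origin.ARTIFICIAL:
            continue
        out.append(n)
    return sorted(out, key=lambda n: (n.feature_count, n.mask))


def representative_models(nodes: Sequence[GraphNode]) -> list[tuple[str, tuple[str, str, int]]]:
    """The first-observed model of each node, as (node_id, provenance).

    "First" is the smallest (run_id, frame_index): runs are ordered
    lexicographically, then frames chronologically within a run.  Reference
    nodes with no matching MD frame return a synthetic reference
    provenance.  Artificial nodes have no model and are an error.
    """
    reps = []
    for n in nodes:
        if n.origin == Origin.ARTIFICIAL:
            raise ValueError(
                f"artificial node {n.node_id} has no pharmacophore model to represent"
            )
        if n.frames:
            reps.append((n.node_id, min(n.frames, key=lambda p: (p[1], p[2]))))
        else:  # reference model never seen in the trajectory
            sys_id = min(n.systems) if n.systems else "reference"
            reps.append((n.node_id, (sys_id, "reference", -1)))
    return reps


def consensus_score(
    hit_table: HitTable, selection: Sequence[str]
) -> dict[str, int]:
    """Common-hits consensus: per molecule, how many selected models hit it.

    Only molecules with score ≥ 1 (retrieved by at least one model) appear
    in the result; everything else was never retrieved.
    """
    if not selection:
        raise ValueError("empty model selection")
    unknown = set(selection) - set(hit_table.model_ids)
    if unknown:
        raise KeyError(f"unknown model ids {sorted(unknown)}")
    scores: dict[str, int] = {}
    for model in set(selection):
        for (mol, mdl) in hit_table.hits:
            if mdl == model:
                scores[mol] = scores.get(mol, 0) + 1
    return scores


def _ranked_blocks(
    scores: Mapping[str, float],
    labels: Mapping[str, str],
    fit_scores: Mapping[str, float] | None = None,
) -> list[tuple[int, int]]:
    """Group retrieved molecules into descending-score tie blocks.

    Returns (n_active, n_decoy) per block.  An optional secondary fit score
    splits ties deterministically; remaining ties stay one block and are
    traversed as a straight ROC segment.
    """
    retrieved = [(m, s) for m, s in scores.items() if s > 0]
    keyed: dict[tuple[float, float], list[str]] = {}
    for mol, s in retrieved:
        fs = (fit_scores or {}).get(mol, 0.0)
        keyed.setdefault((-s, -fs), []).append(mol)
    blocks = []
    for key in sorted(keyed):
        mols = keyed[key]
        a = sum(1 for m in mols if labels[m] == ACTIVE)
        blocks.append((a, len(mols) - a))
    return blocks


def truncated_roc_auc(
    scores: Mapping[str, float],
    labels: Mapping[str, str],
    percent: float,
    fit_scores: Mapping[str, float] | None = None,
) -> float:
    """ROC AUC truncated after the top ``percent``% of the screened database.

    Molecules with score > 0 are ranked by descending score; equal-score
    blocks are traversed as straight ROC segments (trapezoid rule).
    Molecules with score 0 were never retrieved, so the curve simply ends
    at the last retrieved molecule.  The cutoff is ceil(percent/100 · N)
    screened molecules (N = database size); a cutoff landing inside a tie
    block takes the proportional part of the block.  The area under the
    truncated curve is normalised by the false-positive rate reached at the
    cutoff.  Conventions: no actives retrieved within the cutoff → 0.0; a
    cutoff reached with zero decoys (FPR 0) → 1.0.
    """
    if not (0.0 < percent <= 100.0):
        raise ValueError("percent must lie in (0, 100]")
    n_total = len(labels)
    n_act = sum(1 for v in labels.values() if v == ACTIVE)
    n_dec = n_total - n_act
    if n_act == 0 or n_dec == 0:
        raise ValueError("AUC needs at least one active and one decoy")
    cutoff = math.ceil(percent / 100.0 * n_total)
    blocks = _ranked_blocks(scores, labels, fit_scores)

    area = 0.0
    ta = fd = 0.0  # actives / decoys accumulated (may be fractional mid-block)
    screened = 0
    for a, d in blocks:
        size = a + d
        take = min(size, cutoff - screened)
        if take <= 0:
            break
        frac = take / size
        a_t, d_t = a * frac, d * frac
        tpr0, fpr0 = ta / n_act, fd / n_dec
        ta += a_t
        fd += d_t
        tpr1, fpr1 = ta / n_act, fd / n_dec
        area += 0.5 * (tpr0 + tpr1) * (fpr1 - fpr0)
        screened += take
        if screened >= cutoff:
            break
    if ta == 0:
        return 0.0
    if fd == 0:
        return 1.0
    return area / (fd / n_dec)


def screening_summary(
    hit_table: HitTable,
    selection: Sequence[str],
    selection_id: str,
    percents: Sequence[float] = (1, 5, 10, 50, 100),
    n_common_features: int = 0,
) -> ScreeningSummary:
    """Consensus-score a selection and compute its truncated AUC profile."""
    scores = consensus_score(hit_table, selection)
    best_fit = {}
    for (mol, model), fs in hit_table.fit_scores.items():
        if model in set(selection):
            best_fit[mol] = max(best_fit.get(mol, float("-inf")), fs)
    aucs = {
        float(p): truncated_roc_auc(scores, hit_table.labels, p, best_fit or None)
        for p in percents
    }
    return ScreeningSummary(
        selection_id=selection_id,
        n_common_features=n_common_features,
        n_models=len(set(selection)),
        n_hits=len(scores),
        auc_at=aucs,
    )


def _lerp_color(c0: tuple[int, int, int], c1: tuple[int, int, int], t: float) -> str:
    rgb = tuple(round(a + (b - a) * t) for a, b in zip(c0, c1))
    return "#{:02x}{:02x}{:02x}".format(*rgb)


GRAY = "#9e9e9e"
_RED = (211, 47, 47)
_GREEN = (56, 142, 60)


def color_by_metric(
    graph: HGPMGraph, metric: Mapping[int, float]
) -> dict[int, str]:
    """Map a per-node metric in [0, 1] to a red→green scale.

    Artificial nodes are always gray (they were never screened), as are
    nodes missing from the metric.  Values outside [0, 1] are min-max
    normalised first.
    """
    vals = {m: v for m, v in metric.items() if m in graph.nodes}
    if vals and (min(vals.values()) < 0 or max(vals.values()) > 1):
        lo, hi = min(vals.values()), max(vals.values())
        span = hi - lo or 1.0
        vals = {m: (v - lo) / span for m, v in vals.items()}
    colors = {}
    for mask, node in graph.nodes.items():
        if node.origin == Origin.ARTIFICIAL or mask not in vals:
            colors[mask] = GRAY
        else:
            colors[mask] = _lerp_color(_RED, _GREEN, vals[mask])
    return colors
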