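"""Independent brute-force oracles used to validate the production code.

These deliberately work on ``frozenset`` families and per-molecule curve
expansion rather than the bitmask / tie-block routes the package uses, so
agreement is a genuine cross-check.
"""

from __future__ import annotations

import math
from itertools import combinations


def closure_oracle(sets):
    """Naive fixpoint: repeat all-pairs intersection until nothing changes."""
    family = {frozenset(s) for s in sets}
    changed = True
    while changed:
        changed = False
        for a, b in list(combinations(list(family), 2)):
            i = a & b
            if i and i not in family:
                family.add(i)
                changed = True
    return family


def cover_oracle(family):
    """All strict-subset pairs, then cubic removal of transitive edges."""
    members = list(family)
    edges = set()
    for u in members:
        for v in members:
            if u < v and not any(u < w < v for w in members):
                edges.add((u, v))
    return edges


def truncated_auc_oracle(scores, labels, percent):
    """Per-molecule linear expansion of the retrieved-only ROC curve.

    Each molecule of a tie block contributes an equal fractional share of
    the block's actives and decoys, which makes tie blocks straight
    segments; the curve is truncated after ceil(percent/100 * N) screened
    molecules and its area normalised by the final false-positive rate.
    """
    n_total = len(labels)
    n_act = sum(1 for v in labels.values() if v == "active")
    n_dec = n_total - n_act
    cutoff = math.ceil(percent / 100.0 * n_total)
    by_score = {}
    for mol, s in scores.items():
        if s > 0:
            by_score.setdefault(s, []).append(mol)
    increments = []
    for s in sorted(by_score, reverse=True):
        mols = by_score[s]
        a = sum(1 for m in mols if labels[m] == "active")
        d = len(mols) - a
        for _ in mols:
            increments.append((a / len(mols), d / len(mols)))
    increments = increments[:cutoff]
    ta = fd = area = 0.0
    for da, dd in increments:
        tpr0, fpr0 = ta / n_act, fd / n_dec
        ta += da
        fd += dd
        tpr1, fpr1 = ta / n_act, fd / n_dec
        area += 0.5 * (tpr0 + tpr1) * (fpr1 - fpr0)
    if ta == 0:
        return 0.0
    if fd == 0:
        return 1.0
    return area / (fd / n_dec)
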