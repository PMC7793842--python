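"""Synthetic MD-like pharmacophore ensembles with known ground truth.

Real input to this tool is an ensemble of interaction-based pharmacophore
models, one per MD frame.  The generator emulates the statistical texture
of such data without any physics: each feature follows a two-state Markov
chain whose stationary marginal is an exact parameter, optional latent
binding modes switch between per-feature probability profiles (producing
the characteristic multi-branch graphs), and a matched screening library
provides actives enriched for a chosen mode's core features plus sparse
random decoys.  A containment-based screening stub stands in for 3D
pharmacophore alignment, including its known behaviour that models with
fewer than three features cannot be unambiguously aligned and return no
hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import (
    FeatureKey,
    Mode,
    PharmacophoreModel,
    make_feature_key,
)
from .selection import ACTIVE, DECOY, HitTable

__all__ = [
    "FeatureSpec",
    "BindingMode",
    "TrajectoryParams",
    "LibraryParams",
    "default_feature_specs",
    "default_trajectory_params",
    "simulate_trajectory",
    "simulate_library",
    "screening_stub",
    "build_hit_table",
    "MIN_ALIGNABLE_FEATURES",
]

#: Models below this feature count cannot be unambiguously aligned in 3D
#: and retrieve nothing.
MIN_ALIGNABLE_FEATURES = 3


@dataclass(frozen=True)
class FeatureSpec:
    """One feature's Markov dynamics: stationary probability and persistence.

    ``stationary_prob`` p is the exact marginal P(on); ``persistence`` ρ is
    the lag-1 autocorrelation of the on/off trace.  Transitions are
    P(on→on) = p + ρ(1−p) and P(off→on) = p(1−ρ), which leave Bernoulli(p)
    invariant for any ρ ∈ [0, 1).
    """

    key: FeatureKey
    stationary_prob: float
    persistence: float = 0.0

    def __post_init__(self):
        if not (0.0 < self.stationary_prob <= 1.0):
            raise ValueError("stationary_prob must lie in (0, 1]")
        if not (0.0 <= self.persistence < 1.0):
            raise ValueError("persistence must lie in [0, 1)")


@dataclass(frozen=True)
class BindingMode:
    """A latent conformational state with its own stationary probabilities.

    ``probs`` overrides the per-feature stationary probability while the
    mode is occupied; features absent from ``probs`` keep their base value.
    """

    name: str
    probs: dict[str, float]  # feature serial -> stationary prob in this mode


@dataclass
class TrajectoryParams:
    n_frames: int
    features: list[FeatureSpec]
    modes: list[BindingMode] = field(default_factory=list)
    mode_switch_prob: float = 0.0
    system_id: str = "synth"
    run_id: str = "run1"
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be positive")
        if not self.features:
            raise ValueError("at least one feature is required")
        if self.modes and not (0.0 < self.mode_switch_prob < 1.0):
            raise ValueError("modes need a mode_switch_prob in (0, 1)")


@dataclass
class LibraryParams:
    n_actives: int
    n_decoys: int
    core: frozenset[FeatureKey]  # features every ideal active carries
    active_core_prob: float = 0.9  # P(an active carries the full core)
    active_extra_prob: float = 0.3  # P(each non-core feature | active)
    decoy_feature_prob: float = 0.15  # P(each feature | decoy)
    seed: int = 0

    def __post_init__(self):
        if self.n_actives < 1 or self.n_decoys < 1:
            raise ValueError("need at least one active and one decoy")
        for p in (self.active_core_prob, self.active_extra_prob, self.decoy_feature_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")


def _residue(i: int) -> str:
    pool = ("ARG63", "SER64", "THR65", "TYR214", "ILE211", "MET210", "TYR215",
            "VAL62", "GLY97", "PRO66", "LYS169", "ASP205")
    return pool[i % len(pool)] if i < len(pool) else f"RES{i + 100}"


def default_feature_specs(n_features: int = 14, persistence: float = 0.3) -> list[FeatureSpec]:
    """A realistic mixed alphabet for a kinase-like binding site.

    Feature types follow the hydrophobic-heavy composition typical of
    interaction fingerprints (roughly 60% hydrophobic); stationary
    probabilities span stable anchors (~0.9) down to transient contacts
    (~0.05) on a geometric ladder.
    """
    types = ["HBA", "HBD", "H", "H", "AR", "H", "HBA", "H", "H", "XBD",
             "H", "HBD", "H", "AR", "H", "HBA", "H", "H", "PI", "NI"]
    specs = []
    for i in range(n_features):
        ftype = types[i % len(types)]
        p = max(0.03, 0.9 * (0.78**i))
        specs.append(
            FeatureSpec(
                make_feature_key(ftype, [f"A{i + 1}"], [_residue(i)], Mode.LIGAND_AWARE),
                stationary_prob=round(p, 4),
                persistence=persistence,
            )
        )
    return specs


def default_trajectory_params(
    n_frames: int = 2000, seed: int = 0, two_modes: bool = True
) -> TrajectoryParams:
    """Study-like conditions: a two-mode ensemble over the default alphabet.

    The two binding modes share a stable core (the first three features)
    and differ in which extension features are reachable, mirroring the
    two-branch topology seen in multi-conformation MD ensembles.
    """
    specs = default_feature_specs()
    modes: list[BindingMode] = []
    switch = 0.0
    if two_modes:
        serials = [s.key.serial for s in specs]
        # mode 1 favours one half of the transient features, mode 2 the other
        m1 = {s: 0.7 for s in serials[3:8]} | {s: 0.01 for s in serials[8:13]}
        m2 = {s: 0.01 for s in serials[3:8]} | {s: 0.7 for s in serials[8:13]}
        modes = [BindingMode("mode1", m1), BindingMode("mode2", m2)]
        switch = 0.01
    return TrajectoryParams(
        n_frames=n_frames,
        features=specs,
        modes=modes,
        mode_switch_prob=switch,
        seed=seed,
    )


def simulate_trajectory(params: TrajectoryParams) -> list[PharmacophoreModel]:
    """Sample one run: per-feature Markov on/off traces, optional mode switching.

    Frame t's pharmacophore model is the set of features that are "on" at
    t.  With latent modes, a single Markov chain over modes (uniform
    switch target) modulates the per-feature stationary probabilities.
    Fully deterministic under ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    n, feats = params.n_frames, params.features
    k = len(feats)

    if params.modes:
        n_modes = len(params.modes)
        mode_idx = np.empty(n, dtype=int)
        mode_idx[0] = rng.integers(n_modes)
        for t in range(1, n):
            if rng.random() < params.mode_switch_prob:
                mode_idx[t] = rng.integers(n_modes)
            else:
                mode_idx[t] = mode_idx[t - 1]
        p_by_mode = np.empty((n_modes, k))
        for mi, mode in enumerate(params.modes):
            for fi, spec in enumerate(feats):
                p_by_mode[mi, fi] = mode.probs.get(spec.key.serial, spec.stationary_prob)
        p_t = p_by_mode[mode_idx]  # (n, k)
    else:
        p_t = np.tile([s.stationary_prob for s in feats], (n, 1))

    rho = np.array([s.persistence for s in feats])
    u = rng.random((n, k))
    on = np.empty((n, k), dtype=bool)
    on[0] = u[0] < p_t[0]
    for t in range(1, n):
        p = p_t[t]
        p_stay = p + rho * (1.0 - p)  # P(on -> on)
        p_gain = p * (1.0 - rho)  # P(off -> on)
        on[t] = np.where(on[t - 1], u[t] < p_stay, u[t] < p_gain)

    models = []
    for t in range(n):
        present = frozenset(feats[i].key for i in range(k) if on[t, i])
        models.append(
            PharmacophoreModel(params.system_id, params.run_id, t, present)
        )
    return models


def simulate_library(
    params: LibraryParams, universe: list[FeatureKey]
) -> tuple[dict[str, frozenset[FeatureKey]], dict[str, str], dict]:
    """Generate a labelled screening library over *universe*.

    Actives carry the designated core feature set with probability
    ``active_core_prob`` (independent per-feature otherwise) plus random
    extras; decoys are sparse uniform feature sets.  Returns (molecules,
    labels, report) where the report records the realised core-coverage
    rates of both classes.
    """
    if not params.core <= set(universe):
        raise ValueError("core features must lie inside the feature universe")
    rng = np.random.default_rng(params.seed)
    universe = sorted(universe, key=lambda key: key.serial)
    non_core = [k for k in universe if k not in params.core]
    molecules: dict[str, frozenset[FeatureKey]] = {}
    labels: dict[str, str] = {}
    n_act_core = n_dec_core = 0
    for i in range(params.n_actives):
        feats = set()
        if rng.random() < params.active_core_prob:
            feats |= params.core
        else:  # degraded active: each core feature independently
            feats |= {k for k in params.core if rng.random() < 0.5}
        feats |= {k for k in non_core if rng.random() < params.active_extra_prob}
        mid = f"act{i:05d}"
        molecules[mid] = frozenset(feats)
        labels[mid] = ACTIVE
        n_act_core += params.core <= feats
    for i in range(params.n_decoys):
        feats = {k for k in universe if rng.random() < params.decoy_feature_prob}
        mid = f"dec{i:05d}"
        molecules[mid] = frozenset(feats)
        labels[mid] = DECOY
        n_dec_core += params.core <= feats
    report = {
        "active_core_coverage": n_act_core / params.n_actives,
        "decoy_core_coverage": n_dec_core / params.n_decoys,
        "seed": params.seed,
    }
    return molecules, labels, report


def screening_stub(model: frozenset[FeatureKey], molecule: frozenset[FeatureKey]) -> bool:
    """Containment screening: hit iff the model's features are all present.

    Models with fewer than :data:`MIN_ALIGNABLE_FEATURES` features return
    no hits, mimicking the ambiguity of aligning tiny pharmacophores in 3D.
    """
    if len(model) < MIN_ALIGNABLE_FEATURES:
        return False
    return model <= molecule


def build_hit_table(
    models_by_id: dict[str, frozenset[FeatureKey]],
    molecules: dict[str, frozenset[FeatureKey]],
    labels: dict[str, str],
) -> HitTable:
    """Screen every model against every molecule with the containment stub."""
    table = HitTable(labels, models_by_id.keys())
    for model_id, model in sorted(models_by_id.items()):
        for mol_id, feats in molecules.items():
            if screening_stub(model, feats):
                table.add_hit(mol_id, model_id)
    return table
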