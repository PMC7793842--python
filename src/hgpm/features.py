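"""Feature identity, feature vectors, and appearance-count bookkeeping.

The alphabet of the whole method is the *unique pharmacophore feature*: an
interaction is identified by its chemical feature type, the ligand atoms it
involves, and the protein residues it touches — never by 3D position.  Every
frame of an MD trajectory contributes one pharmacophore model (a set of such
features), and the ensemble is summarised as counted unique binary feature
vectors over the catalog of all features ever observed.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "FEATURE_TYPES",
    "Mode",
    "FeatureKey",
    "PharmacophoreModel",
    "FeatureCatalog",
    "CountedVector",
    "VocabularyError",
    "InvalidFeatureError",
    "ModeMismatchError",
    "CatalogCoverageError",
    "make_feature_key",
    "parse_feature_key",
    "build_catalog",
    "vectorize",
    "count_unique",
    "filter_by_count",
    "run_overlap",
    "type_composition",
]

#: Interaction feature types: hydrophobic, aromatic ring, hydrogen-bond
#: acceptor/donor, positive/negative ionizable area, halogen-bond donor.
FEATURE_TYPES = ("H", "AR", "HBA", "HBD", "PI", "NI", "XBD")

_SEP = "|"
_LIST_SEP = ","


class Mode:
    """Feature-serial generation modes.

    ``LIGAND_AWARE`` keeps the ligand atoms in the feature identity, so the
    same residue contact through different ligand atoms yields distinct
    features.  ``PROJECTED`` drops the ligand side entirely, projecting the
    interaction onto the protein so ensembles of different ligands against
    one target become comparable.
    """

    LIGAND_AWARE = "ligand_aware"
    PROJECTED = "projected"
    ALL = (LIGAND_AWARE, PROJECTED)


class VocabularyError(ValueError):
    """Unknown pharmacophore feature type."""


class InvalidFeatureError(ValueError):
    """Feature violates a structural precondition (e.g. no residues)."""


class ModeMismatchError(ValueError):
    """Inputs mix ligand-aware and projected feature serials."""


class CatalogCoverageError(KeyError):
    """A model contains a feature absent from the catalog."""


def _check_identifier(value: str, what: str) -> str:
    if not value:
        raise InvalidFeatureError(f"empty {what} identifier")
    if _SEP in value or _LIST_SEP in value:
        raise InvalidFeatureError(
            f"{what} identifier {value!r} contains reserved characters '|' or ','"
        )
    return value


@dataclass(frozen=True, order=True)
class FeatureKey:
    """Canonical identity of one unique pharmacophore feature.

    Ordering and equality are defined by the canonical serial string, which
    is injective within a mode (identifiers may not contain the separator
    characters).  Use :func:`make_feature_key` rather than the constructor;
    it applies sorting, deduplication and validation.
    """

    feature_type: str
    ligand_part: tuple[str, ...]
    environment: tuple[str, ...]
    mode: str

    @property
    def serial(self) -> str:
        if self.mode == Mode.PROJECTED:
            return _SEP.join((self.feature_type, _LIST_SEP.join(self.environment)))
        return _SEP.join(
            (
                self.feature_type,
                _LIST_SEP.join(self.ligand_part),
                _LIST_SEP.join(self.environment),
            )
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.serial

    def projected(self) -> "FeatureKey":
        """Project onto the protein side (drop ligand atoms)."""
        return FeatureKey(self.feature_type, (), self.environment, Mode.PROJECTED)


def make_feature_key(
    feature_type: str,
    ligand_atoms: Sequence[str],
    residues: Sequence[str],
    mode: str = Mode.LIGAND_AWARE,
) -> FeatureKey:
    """Build a canonical :class:`FeatureKey`.

    Ligand atoms and residues are sorted and deduplicated.  In projected
    mode the ligand atoms are discarded, so two ligand-aware features that
    differ only in their ligand part collapse onto one projected key.
    """
    if feature_type not in FEATURE_TYPES:
        raise VocabularyError(
            f"unknown feature type {feature_type!r}; expected one of {FEATURE_TYPES}"
        )
    if mode not in Mode.ALL:
        raise ModeMismatchError(f"unknown mode {mode!r}")
    if not residues:
        raise InvalidFeatureError("a feature needs at least one environment residue")
    env = tuple(sorted({_check_identifier(r, "residue") for r in residues}))
    if mode == Mode.PROJECTED:
        lig: tuple[str, ...] = ()
    else:
        if not ligand_atoms:
            raise InvalidFeatureError(
                "ligand-aware features need at least one ligand atom"
            )
        lig = tuple(sorted({_check_identifier(a, "ligand atom") for a in ligand_atoms}))
    return FeatureKey(feature_type, lig, env, mode)


def parse_feature_key(serial: str, mode: str) -> FeatureKey:
    """Inverse of :attr:`FeatureKey.serial` for the given mode."""
    parts = serial.split(_SEP)
    expected = 2 if mode == Mode.PROJECTED else 3
    if len(parts) != expected:
        raise InvalidFeatureError(
            f"serial {serial!r} has {len(parts)} fields, expected {expected} for mode {mode!r}"
        )
    if mode == Mode.PROJECTED:
        ftype, env = parts
        return make_feature_key(ftype, (), env.split(_LIST_SEP), mode)
    ftype, lig, env = parts
    return make_feature_key(ftype, lig.split(_LIST_SEP), env.split(_LIST_SEP), mode)


@dataclass(frozen=True)
class PharmacophoreModel:
    """One frame's pharmacophore model with provenance.

    ``payload_ref`` is an opaque handle to an external 3D model (never
    interpreted here); ``is_reference`` marks crystal-structure-derived
    models, which bypass appearance-count filtering downstream.
    """

    system_id: str
    run_id: str
    frame_index: int
    features: frozenset[FeatureKey]
    payload_ref: str | None = None
    is_reference: bool = False

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")
        modes = {k.mode for k in self.features}
        if len(modes) > 1:
            raise ModeMismatchError(
                f"model ({self.system_id},{self.run_id},{self.frame_index}) mixes modes {sorted(modes)}"
            )

    @property
    def provenance(self) -> tuple[str, str, int]:
        return (self.system_id, self.run_id, self.frame_index)

    def project(self) -> "PharmacophoreModel":
        """Return the same model with every feature projected onto the protein."""
        return PharmacophoreModel(
            self.system_id,
            self.run_id,
            self.frame_index,
            frozenset(k.projected() for k in self.features),
            self.payload_ref,
            self.is_reference,
        )


class FeatureCatalog:
    """Ordered, duplicate-free list of all unique features of an ensemble.

    The order is the lexicographic order of the canonical serials, which
    fixes the bit position of every feature reproducibly across runs.
    """

    def __init__(self, entries: Iterable[FeatureKey], mode: str | None = None):
        uniq = sorted(set(entries), key=lambda k: k.serial)
        modes = {k.mode for k in uniq}
        if len(modes) > 1:
            raise ModeMismatchError(f"catalog mixes modes {sorted(modes)}")
        if mode is None:
            if not modes:
                raise ValueError("empty catalog needs an explicit mode")
            mode = modes.pop()
        elif modes and modes != {mode}:
            raise ModeMismatchError(f"entries have mode {modes.pop()!r}, not {mode!r}")
        self.entries: tuple[FeatureKey, ...] = tuple(uniq)
        self.mode = mode
        self._index = {k: i for i, k in enumerate(self.entries)}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __contains__(self, key: FeatureKey) -> bool:
        return key in self._index

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FeatureCatalog)
            and self.mode == other.mode
            and self.entries == other.entries
        )

    def index(self, key: FeatureKey) -> int:
        try:
            return self._index[key]
        except KeyError:
            raise CatalogCoverageError(
                f"feature {key.serial!r} is not in the catalog"
            ) from None

    def to_mask(self, features: Iterable[FeatureKey]) -> int:
        """Encode a feature set as an integer bitmask (bit i = entry i)."""
        mask = 0
        for k in features:
            mask |= 1 << self.index(k)
        return mask

    def from_mask(self, mask: int) -> frozenset[FeatureKey]:
        return frozenset(
            self.entries[i] for i in range(len(self.entries)) if mask >> i & 1
        )

    def bits_string(self, mask: int) -> str:
        """'101…' string, position 0 first (catalog order left to right)."""
        return "".join("1" if mask >> i & 1 else "0" for i in range(len(self.entries)))

    def mask_from_bits(self, bits: str) -> int:
        if len(bits) != len(self.entries):
            raise CatalogCoverageError(
                f"bit string length {len(bits)} != catalog size {len(self.entries)}"
            )
        return sum(1 << i for i, b in enumerate(bits) if b == "1")


@dataclass
class CountedVector:
    """A unique feature vector with its appearance count and frame list.

    ``appearance_count`` is the number of frames whose model's feature set
    equals the vector exactly.  ``frames`` is sorted by (run_id,
    frame_index) so "the first model observed" is always ``frames[0]``.
    """

    mask: int
    appearance_count: int
    frames: list[tuple[str, str, int]] = field(default_factory=list)
    observed: bool = True
    reference: bool = False
    payload_refs: dict[tuple[str, str, int], str] = field(default_factory=dict)


def build_catalog(models: Sequence[PharmacophoreModel]) -> FeatureCatalog:
    """Catalog of all unique features across *models* (order-independent)."""
    if not models:
        raise ValueError("cannot build a catalog from an empty model list")
    modes = {k.mode for m in models for k in m.features}
    if len(modes) > 1:
        raise ModeMismatchError(f"models mix modes {sorted(modes)}")
    keys: set[FeatureKey] = set()
    for m in models:
        keys.update(m.features)
    return FeatureCatalog(keys, mode=modes.pop() if modes else Mode.LIGAND_AWARE)


def vectorize(
    models: Sequence[PharmacophoreModel], catalog: FeatureCatalog
) -> tuple[list[tuple[int, PharmacophoreModel]], list[tuple[str, str, int]]]:
    """Convert models to (bitmask, model) pairs over *catalog*.

    Models with an empty feature set produce no vector; their provenance is
    returned separately so callers can log and count them.
    """
    vectors: list[tuple[int, PharmacophoreModel]] = []
    skipped: list[tuple[str, str, int]] = []
    for m in models:
        if not m.features:
            skipped.append(m.provenance)
            continue
        vectors.append((catalog.to_mask(m.features), m))
    return vectors, skipped


def count_unique(vectors: Sequence[tuple[int, PharmacophoreModel]]) -> list[CountedVector]:
    """Deduplicate vectors, counting appearances and collecting frames.

    Reference (crystal-structure) models do not add to the appearance
    count — that counts MD frames only — but they mark the vector as a
    reference vector.  The result is sorted by bitmask for determinism.
    """
    by_mask: dict[int, CountedVector] = {}
    for mask, model in vectors:
        cv = by_mask.get(mask)
        if cv is None:
            cv = by_mask[mask] = CountedVector(mask, 0, [], observed=False)
        if model.is_reference:
            cv.reference = True
        else:
            cv.observed = True
            cv.appearance_count += 1
            cv.frames.append(model.provenance)
        if model.payload_ref is not None:
            cv.payload_refs[model.provenance] = model.payload_ref
    out = sorted(by_mask.values(), key=lambda c: c.mask)
    for cv in out:
        cv.frames.sort(key=lambda p: (p[1], p[2]))
    return out


def filter_by_count(
    counted: Sequence[CountedVector],
    min_count: int | None = None,
    fraction: float | None = None,
    n_frames: int | None = None,
) -> tuple[list[CountedVector], int]:
    """Drop rare unique vectors; returns (survivors, threshold used).

    Exactly one of ``min_count`` / ``fraction`` must be given.  The
    fractional threshold is ``floor(fraction * n_frames)`` but never below
    2, the baseline noise filter (a vector seen once is noise).  Reference
    vectors are exempt and always kept.
    """
    if (min_count is None) == (fraction is None):
        raise ValueError("give exactly one of min_count or fraction")
    if min_count is not None:
        if min_count < 1:
            raise ValueError("min_count must be positive")
        threshold = min_count
    else:
        if not (0.0 < fraction < 1.0):
            raise ValueError("fraction must lie in (0, 1)")
        if n_frames is None or n_frames < 1:
            raise ValueError("fraction thresholds need n_frames")
        threshold = max(2, math.floor(fraction * n_frames))
    kept = [
        cv for cv in counted if cv.reference or cv.appearance_count >= threshold
    ]
    return kept, threshold


def run_overlap(
    catalogs_by_run: Mapping[str, set[FeatureKey]],
) -> tuple[dict[frozenset[str], int], int]:
    """Venn-region counts of unique features across simulation runs.

    Returns ``(regions, union_size)`` where ``regions`` maps each non-empty
    subset of run ids to the number of features observed in exactly those
    runs.  Region counts sum to the union size by construction.
    """
    if len(catalogs_by_run) < 2:
        raise ValueError("run overlap needs at least 2 runs")
    membership: dict[FeatureKey, set[str]] = {}
    for run_id, keys in catalogs_by_run.items():
        for k in keys:
            membership.setdefault(k, set()).add(run_id)
    regions: Counter[frozenset[str]] = Counter(
        frozenset(runs) for runs in membership.values()
    )
    return dict(regions), len(membership)


def type_composition(catalog: FeatureCatalog) -> dict[str, int]:
    """Count catalog entries per feature type (all types present, even at 0)."""
    counts = dict.fromkeys(FEATURE_TYPES, 0)
    for k in catalog:
        counts[k.feature_type] += 1
    return counts
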