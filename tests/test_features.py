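"""Feature identity, vectorization and counting."""

import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hgpm import (
    FeatureCatalog,
    Mode,
    build_catalog,
    count_unique,
    filter_by_count,
    make_feature_key,
    parse_feature_key,
    run_overlap,
    type_composition,
    vectorize,
)
from hgpm.features import (
    FEATURE_TYPES,
    InvalidFeatureError,
    ModeMismatchError,
    VocabularyError,
)

from conftest import key, model


class TestFeatureKey:
    def test_canonical_serial(self):
        k = make_feature_key("HBA", ["N1"], ["ARG63"])
        assert k.serial == "HBA|N1|ARG63"

    def test_projection_drops_ligand_atoms(self):
        a = make_feature_key("HBA", ["N1"], ["ARG63"], Mode.PROJECTED)
        b = make_feature_key("HBA", ["O2"], ["ARG63"], Mode.PROJECTED)
        assert a == b
        assert a.serial == "HBA|ARG63"

    def test_projected_method_is_many_to_one(self):
        a = make_feature_key("H", ["F1"], ["ILE211"])
        b = make_feature_key("H", ["C9"], ["ILE211"])
        assert a != b
        assert a.projected() == b.projected()

    def test_environment_distinguishes_hydrophobic_features(self):
        # same ligand atom, nested residue environments: still distinct
        a = make_feature_key("H", ["F1"], ["ILE211", "TYR214", "TYR215"])
        b = make_feature_key(
            "H", ["F1"], ["THR65", "MET210", "ILE211", "TYR214", "TYR215"]
        )
        assert a != b

    def test_sorting_and_dedup(self):
        k = make_feature_key("H", ["C2", "C1", "C2"], ["TYR214", "ILE211"])
        assert k.ligand_part == ("C1", "C2")
        assert k.environment == ("ILE211", "TYR214")

    def test_vocabulary_error_names_offender(self):
        with pytest.raises(VocabularyError, match="HY"):
            make_feature_key("HY", ["C1"], ["ARG63"])

    def test_empty_residues_rejected(self):
        with pytest.raises(InvalidFeatureError):
            make_feature_key("H", ["C1"], [])

    def test_ligand_atoms_required_in_ligand_aware_mode(self):
        with pytest.raises(InvalidFeatureError):
            make_feature_key("H", [], ["ARG63"])

    @pytest.mark.parametrize("mode", Mode.ALL)
    def test_serial_round_trip(self, mode):
        for i in range(10):
            k = key(i, mode)
            assert parse_feature_key(k.serial, mode) == k

    def test_serialization_injective_within_mode(self):
        # exhaustive small alphabet: 3 types x atom subsets x residue subsets
        atoms = ["C1", "N2"]
        residues = ["ARG63", "SER64"]
        keys = []
        for t in ("H", "HBA", "HBD"):
            for na in (1, 2):
                for la in itertools.combinations(atoms, na):
                    for nr in (1, 2):
                        for env in itertools.combinations(residues, nr):
                            keys.append(make_feature_key(t, la, env))
        serials = [k.serial for k in keys]
        assert len(set(serials)) == len(set(keys)) == len(keys)

    def test_reserved_characters_rejected(self):
        with pytest.raises(InvalidFeatureError):
            make_feature_key("H", ["C|1"], ["ARG63"])


class TestCatalog:
    def test_union_of_models(self):
        models = [model({key(0), key(1)}), model({key(1), key(2)}, frame=1)]
        cat = build_catalog(models)
        assert set(cat) == {key(0), key(1), key(2)}

    def test_order_is_serial_lexicographic_and_permutation_invariant(self):
        models = [model({key(i)}, frame=i) for i in range(6)]
        cat1 = build_catalog(models)
        cat2 = build_catalog(list(reversed(models)))
        assert cat1 == cat2
        serials = [k.serial for k in cat1]
        assert serials == sorted(serials)

    def test_three_run_union(self):
        # per-run unions {a,b}, {b,c}, {b,d} -> 4 unique features
        runs = [
            model({key(0), key(1)}, run="run1"),
            model({key(1), key(2)}, run="run2"),
            model({key(1), key(3)}, run="run3"),
        ]
        assert len(build_catalog(runs)) == 4

    def test_mixed_modes_rejected(self):
        models = [model({key(0)}), model({key(1, Mode.PROJECTED)}, frame=1)]
        with pytest.raises(ModeMismatchError):
            build_catalog(models)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_catalog([])


class TestVectorize:
    def test_bit_positions(self, abc_catalog):
        m = model({key(0), key(2)})
        vectors, skipped = vectorize([m], abc_catalog)
        assert not skipped
        mask = vectors[0][0]
        expected = (1 << abc_catalog.index(key(0))) | (1 << abc_catalog.index(key(2)))
        assert mask == expected
        assert mask.bit_count() == 2

    def test_empty_models_skipped_and_reported(self, abc_catalog):
        ms = [model(set(), frame=0), model({key(1)}, frame=1)]
        vectors, skipped = vectorize(ms, abc_catalog)
        assert len(vectors) == 1
        assert skipped == [("sys", "run1", 0)]

    def test_popcount_matches_feature_set_size(self, rng):
        universe = [key(i) for i in range(6)]
        cat = FeatureCatalog(universe)
        models = []
        for f in range(5):
            feats = {k for k in universe if rng.random() < 0.5} or {universe[0]}
            models.append(model(feats, frame=f))
        vectors, _ = vectorize(models, cat)
        for mask, m in vectors:
            assert mask.bit_count() == len(m.features)

    def test_feature_outside_catalog_errors(self, abc_catalog):
        from hgpm.features import CatalogCoverageError

        with pytest.raises(CatalogCoverageError):
            vectorize([model({key(7)})], abc_catalog)


class TestCountUnique:
    def test_grouping_and_conservation(self, abc_catalog):
        ms = [
            model({key(0), key(1)}, frame=0),
            model({key(0), key(1)}, frame=1),
            model({key(1), key(2)}, frame=2),
        ]
        vectors, _ = vectorize(ms, abc_catalog)
        counted = count_unique(vectors)
        assert len(counted) == 2
        assert sum(c.appearance_count for c in counted) == 3
        by_mask = {c.mask: c for c in counted}
        assert by_mask[abc_catalog.to_mask({key(0), key(1)})].appearance_count == 2
        assert by_mask[abc_catalog.to_mask({key(1), key(2)})].appearance_count == 1

    def test_frames_sorted_run_major(self, abc_catalog):
        ms = [
            model({key(0)}, frame=17, run="run2"),
            model({key(0)}, frame=40, run="run1"),
        ]
        vectors, _ = vectorize(ms, abc_catalog)
        (cv,) = count_unique(vectors)
        assert cv.frames == [("sys", "run1", 40), ("sys", "run2", 17)]

    def test_reference_models_flag_but_do_not_count(self, abc_catalog):
        ms = [
            model({key(0)}, frame=0),
            model({key(0)}, frame=0, run="xray", reference=True),
        ]
        vectors, _ = vectorize(ms, abc_catalog)
        (cv,) = count_unique(vectors)
        assert cv.reference and cv.observed
        assert cv.appearance_count == 1


class TestFilterByCount:
    def test_min_count_threshold(self, abc_catalog):
        ms = [model({key(0)}, frame=f) for f in range(5)] + [model({key(1)}, frame=5)]
        counted = count_unique(vectorize(ms, abc_catalog)[0])
        kept, threshold = filter_by_count(counted, min_count=2)
        assert threshold == 2
        assert len(kept) == 1
        assert kept[0].appearance_count == 5

    def test_fractional_threshold_floors(self):
        _, threshold = filter_by_count([], fraction=0.001, n_frames=10001)
        assert threshold == 10

    def test_fractional_threshold_never_below_two(self):
        _, threshold = filter_by_count([], fraction=0.001, n_frames=500)
        assert threshold == 2

    def test_identity_when_all_pass(self, abc_catalog):
        ms = [model({key(0)}, frame=f) for f in range(3)]
        counted = count_unique(vectorize(ms, abc_catalog)[0])
        kept, _ = filter_by_count(counted, min_count=2)
        assert kept == counted

    def test_reference_vectors_exempt(self, abc_catalog):
        ms = [model({key(0)}, frame=0, reference=True),
              model({key(1)}, frame=1)]
        counted = count_unique(vectorize(ms, abc_catalog)[0])
        kept, _ = filter_by_count(counted, min_count=5)
        assert len(kept) == 1 and kept[0].reference

    def test_exactly_one_threshold_spec(self):
        with pytest.raises(ValueError):
            filter_by_count([], min_count=2, fraction=0.1, n_frames=10)
        with pytest.raises(ValueError):
            filter_by_count([])
        with pytest.raises(ValueError):
            filter_by_count([], fraction=1.5, n_frames=10)


class TestRunOverlap:
    def test_worked_example(self):
        regions, union = run_overlap(
            {"r1": {key(0), key(1)}, "r2": {key(1), key(2)}, "r3": {key(1), key(3)}}
        )
        assert union == 4
        assert regions[frozenset({"r1", "r2", "r3"})] == 1
        assert sum(regions.values()) == union

    def test_identical_runs_all_common(self):
        s = {key(0), key(1)}
        regions, union = run_overlap({"r1": set(s), "r2": set(s)})
        assert regions == {frozenset({"r1", "r2"}): 2}
        assert union == 2

    def test_matches_brute_force_enumeration(self, rng):
        universe = [key(i) for i in range(20)]
        runs = {
            f"r{j}": {k for k in universe if rng.random() < 0.4} for j in range(3)
        }
        regions, union = run_overlap(runs)
        for pattern, count in regions.items():
            brute = sum(
                1
                for k in universe
                if {r for r, s in runs.items() if k in s} == set(pattern)
            )
            assert count == brute
        assert union == len(set().union(*runs.values()))

    def test_needs_two_runs(self):
        with pytest.raises(ValueError):
            run_overlap({"r1": {key(0)}})


class TestTypeComposition:
    def test_counts_by_type(self):
        cat = FeatureCatalog(
            [
                make_feature_key("H", ["C1"], ["ARG63"]),
                make_feature_key("H", ["C2"], ["SER64"]),
                make_feature_key("HBA", ["N1"], ["ARG63"]),
            ]
        )
        comp = type_composition(cat)
        assert comp["H"] == 2 and comp["HBA"] == 1
        assert sum(comp.values()) == len(cat)

    def test_empty_catalog(self):
        comp = type_composition(FeatureCatalog([], mode=Mode.LIGAND_AWARE))
        assert set(comp) == set(FEATURE_TYPES)
        assert sum(comp.values()) == 0


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    sets=st.lists(
        st.frozensets(st.integers(min_value=0, max_value=7), min_size=0, max_size=6),
        min_size=1,
        max_size=25,
    ),
    perm_seed=st.integers(min_value=0, max_value=10_000),
)
def test_counting_is_order_invariant_and_conservative(sets, perm_seed):
    """Catalog, counts and filtered sets are permutation-invariant, and
    appearance counts sum to the number of non-empty models."""
    models = [model({key(i) for i in s}, frame=f) for f, s in enumerate(sets)]
    if all(not m.features for m in models):
        return
    shuffled = models[:]
    random.Random(perm_seed).shuffle(shuffled)

    cat1, cat2 = build_catalog(models), build_catalog(shuffled)
    assert cat1 == cat2
    v1, skipped1 = vectorize(models, cat1)
    v2, _ = vectorize(shuffled, cat2)
    c1, c2 = count_unique(v1), count_unique(v2)
    assert [(c.mask, c.appearance_count, c.frames) for c in c1] == [
        (c.mask, c.appearance_count, c.frames) for c in c2
    ]
    assert sum(c.appearance_count for c in c1) == len(models) - len(skipped1)
    k1, _ = filter_by_count(c1, min_count=2)
    k2, _ = filter_by_count(c2, min_count=2)
    assert [c.mask for c in k1] == [c.mask for c in k2]
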