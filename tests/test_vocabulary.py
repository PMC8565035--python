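"""Concept store: resolution, custom concepts, ancestor closure."""

import copy

import pytest
from hypothesis import given, settings, strategies as st

from omopmap.vocabulary import (
    CUSTOM_ID_START,
    Concept,
    ConceptRelationship,
    CrosswalkEntry,
    VocabularyStore,
    combine_concepts,
    load_vocabulary,
)


def brute_force_closure(edges, nodes):
    """Exhaustive DFS path enumeration: {(anc, desc): (min, max)} levels."""
    children = {}
    for child, parent in edges:
        children.setdefault(child, []).append(parent)
    result = {(n, n): (0, 0) for n in nodes}

    def walk(start, node, depth):
        for parent in children.get(node, []):
            key = (parent, start)
            lo, hi = result.get(key, (depth + 1, depth + 1))
            result[key] = (min(lo, depth + 1), max(hi, depth + 1))
            walk(start, parent, depth + 1)

    for n in nodes:
        walk(n, n, 0)
    return result


def make_store(n_nodes, edges):
    store = VocabularyStore()
    for i in range(n_nodes):
        store.add_concept(Concept(i + 1, f"c{i + 1}", "Condition", "SNOMED"))
    for child, parent in edges:
        store.add_relationship(ConceptRelationship(child, parent, "Is a"))
    return store


class TestAncestorClosure:
    def test_chain(self):
        # D is-a B, B is-a A: closure carries both direct and 2-level rows
        store = make_store(3, [(3, 2), (2, 1)])
        rows = {(a.ancestor_id, a.descendant_id): (a.min_levels, a.max_levels)
                for a in store.build_ancestor_closure()}
        assert rows == {
            (1, 1): (0, 0), (2, 2): (0, 0), (3, 3): (0, 0),
            (1, 2): (1, 1), (2, 3): (1, 1), (1, 3): (2, 2),
        }

    def test_diamond_and_shortcut_edge(self):
        diamond = make_store(4, [(4, 2), (4, 3), (2, 1), (3, 1)])
        rows = {(a.ancestor_id, a.descendant_id): (a.min_levels, a.max_levels)
                for a in diamond.build_ancestor_closure()}
        assert rows[(1, 4)] == (2, 2)
        shortcut = make_store(4, [(4, 2), (4, 3), (2, 1), (3, 1), (4, 1)])
        rows = {(a.ancestor_id, a.descendant_id): (a.min_levels, a.max_levels)
                for a in shortcut.build_ancestor_closure()}
        assert rows[(1, 4)] == (1, 2)

    def test_empty_relationships_yield_self_rows_only(self):
        store = make_store(3, [])
        rows = store.build_ancestor_closure()
        assert {(a.ancestor_id, a.descendant_id) for a in rows} == {
            (1, 1), (2, 2), (3, 3)
        }
        assert all(a.min_levels == a.max_levels == 0 for a in rows)

    def test_cycle_is_fatal_and_named(self):
        store = make_store(3, [(1, 2), (2, 3), (3, 1)])
        with pytest.raises(ValueError, match="cycle"):
            store.build_ancestor_closure()

    @given(st.data())
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_matches_brute_force_oracle_on_random_dags(self, data):
        n = data.draw(st.integers(2, 50))
        # edges only child(higher) -> parent(lower): acyclic by construction
        edges = data.draw(
            st.lists(
                st.tuples(st.integers(2, n), st.integers(1, n - 1)).filter(
                    lambda e: e[0] > e[1]
                ),
                max_size=120, unique=True,
            )
        )
        store = make_store(n, edges)
        rows = {(a.ancestor_id, a.descendant_id): (a.min_levels, a.max_levels)
                for a in store.build_ancestor_closure()}
        assert rows == brute_force_closure(edges, range(1, n + 1))


class TestResolution:
    def test_catheter_site_discharge_fans_out(self, store):
        targets, provenance = store.resolve_source("MedDRA", "10057688")
        assert targets == [4249456, 4183956]
        assert provenance == "manual"

    def test_unmapped_source_yields_empty(self, store):
        assert store.resolve_source("free-text", "zzz-nonsense") == ([], None)

    def test_free_text_custom_concept(self, store):
        targets, provenance = store.resolve_source(
            "free-text", "drug- and toxin-induced PAH"
        )
        assert provenance == "custom"
        assert len(targets) == 1 and targets[0] >= CUSTOM_ID_START

    def test_maps_to_fallback_for_coded_nonstandard(self, store):
        # WHODrug concepts resolve through their 'Maps to' edge when the
        # crosswalk is silent
        trimmed = copy.deepcopy(store)
        trimmed.crosswalk.clear()
        targets, provenance = trimmed.resolve_source("WHODrug", "WD000101")
        assert targets == [42000001]
        assert provenance == "maps_to"

    def test_resolution_is_deterministic(self, store):
        first = store.resolve_source("MedDRA", "10057688")
        assert all(
            store.resolve_source("MedDRA", "10057688") == first
            for _ in range(3)
        )


class TestCustomConcepts:
    def test_registration_allocates_from_custom_range(self, store):
        s = copy.deepcopy(store)
        cid = s.register_custom_concept("Test subgroup", "Condition", [37000001])
        assert cid >= CUSTOM_ID_START
        assert any(
            r.concept_id_1 == cid and r.concept_id_2 == 37000001
            and r.relationship_id == "Is a"
            for r in s.relationships
        )
        assert s.closure_stale

    def test_registration_is_idempotent(self, store):
        s = copy.deepcopy(store)
        a = s.register_custom_concept("Same name", "Observation", [])
        b = s.register_custom_concept("Same name", "Observation", [])
        assert a == b

    def test_orphan_custom_concept_permitted(self, store):
        s = copy.deepcopy(store)
        cid = s.register_custom_concept("WHO functional grading", "Observation", [])
        assert s.concepts[cid].is_custom

    def test_unknown_parent_is_fatal(self, store):
        s = copy.deepcopy(store)
        with pytest.raises(KeyError):
            s.register_custom_concept("Bad", "Condition", [999999999])

    def test_registration_never_alters_standard_content(self, store):
        s = copy.deepcopy(store)
        before_concepts = dict(s.concepts)
        before_rels = list(s.relationships)
        closure_before = {
            (a.ancestor_id, a.descendant_id): (a.min_levels, a.max_levels)
            for a in s.build_ancestor_closure()
            if a.ancestor_id < CUSTOM_ID_START
            and a.descendant_id < CUSTOM_ID_START
        }
        s.register_custom_concept("New subgroup", "Condition", [4322024])
        assert all(s.concepts[cid] == c for cid, c in before_concepts.items())
        assert s.relationships[: len(before_rels)] == before_rels
        closure_after = {
            (a.ancestor_id, a.descendant_id): (a.min_levels, a.max_levels)
            for a in s.build_ancestor_closure()
            if a.ancestor_id < CUSTOM_ID_START
            and a.descendant_id < CUSTOM_ID_START
        }
        assert closure_after == closure_before


class TestStoreIntegrity:
    def test_maps_to_must_target_standard(self):
        store = VocabularyStore()
        store.add_concept(Concept(1, "src", "Condition", "MedDRA", "classification"))
        store.add_concept(Concept(2, "cls", "Condition", "MedDRA", "classification"))
        with pytest.raises(ValueError, match="not standard"):
            store.add_relationship(ConceptRelationship(1, 2, "Maps to"))

    def test_crosswalk_target_must_exist(self):
        store = VocabularyStore()
        with pytest.raises(KeyError):
            store.add_crosswalk_entry(CrosswalkEntry("MedDRA", "1", (42,)))

    def test_combination_recipe(self, store):
        combo = combine_concepts(37000001, [37000003], store)
        assert combo.concept_ids == (37000001, 37000003)
        assert combine_concepts(37000001, [], store).concept_ids == (37000001,)

    def test_round_trip_through_athena_layout(self, store, tmp_path):
        store.write(tmp_path)
        loaded = load_vocabulary(tmp_path)
        assert loaded.concepts == store.concepts
        assert loaded.relationships == store.relationships
        assert loaded.ancestors == store.ancestors
        assert set(loaded.crosswalk) == set(store.crosswalk)
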