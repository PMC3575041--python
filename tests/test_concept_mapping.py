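"""Direct and indirect mapping semantics on hand-built knowledge bases."""

import dataclasses

import pytest

from conftest import C1, C2, D1, D2, G1, G2, X1
from clingenmap.concept_mapping import (
    CandidateRelation,
    ConceptSet,
    MappingConfig,
    combine_candidates,
    direct_map,
    diseases_for,
    filter_by_semantic_type,
    indirect_map,
    read_relations_tsv,
    related_concepts,
    resolve_cuis,
    write_relations_tsv,
)
from clingenmap.rrf_io import (
    ConceptRelation,
    build_kb,
)


class TestResolveCuis:
    def test_absent_term_gives_empty_set(self, tiny_kb):
        assert resolve_cuis("no such concept", tiny_kb) == frozenset()

    def test_unique_term_gives_singleton(self, tiny_kb):
        assert resolve_cuis("gene alpha", tiny_kb) == {G1}

    def test_ambiguous_term_returns_all_cuis(self, tiny_kb):
        assert resolve_cuis("shared term", tiny_kb) == {G1, G2}

    def test_source_code_reference(self, tiny_kb):
        assert resolve_cuis("SNOMEDCT:201", tiny_kb) == {C1}
        assert resolve_cuis("SNOMEDCT:99999", tiny_kb) == frozenset()

    def test_explicit_cui_reference(self, tiny_kb):
        assert resolve_cuis(f"CUI:{D1}", tiny_kb) == {D1}
        assert resolve_cuis("CUI:C9999999", tiny_kb) == frozenset()

    def test_suppressed_atoms_excluded_by_default(self, tiny_kb):
        assert resolve_cuis("old alpha name", tiny_kb) == frozenset()
        assert resolve_cuis("old alpha name", tiny_kb,
                            include_suppressed=True) == {G1}


class TestRelatedConcepts:
    def test_cui_without_qualifying_rows_has_no_neighbours(self, tiny_kb):
        # G2's only relation row is suppressed
        assert related_concepts(G2, tiny_kb, MappingConfig()) == frozenset()

    def test_cooccurrence_counterpart_found_from_either_side(self, tiny_kb):
        assert related_concepts(X1, tiny_kb, MappingConfig()) == {G1}

    def test_union_of_mrrel_and_mrcoc(self, tiny_kb):
        # G1: MRREL to C1, MRCOC to D1 (freq 2), D2 (freq 1), X1 (freq 4);
        # the self-relation row is excluded.
        assert related_concepts(G1, tiny_kb, MappingConfig()) == {C1, D1, D2, X1}

    def test_cooccurrence_threshold_drops_low_frequency(self, tiny_kb):
        config = MappingConfig(min_cooccurrence_frequency=2)
        assert related_concepts(G1, tiny_kb, config) == {C1, D1, X1}

    def test_suppressed_relation_rows_ignored(self, tiny_kb):
        config = MappingConfig(use_mrcoc=False)
        assert related_concepts(G2, tiny_kb, config) == frozenset()
        config = MappingConfig(use_mrcoc=False, include_suppressed=True)
        assert related_concepts(G2, tiny_kb, config) == {C2}

    def test_directed_walk_uses_cui1_side_only(self, tiny_kb):
        config = MappingConfig(treat_relations_as_bidirectional=False,
                               use_mrcoc=False)
        # C1 appears as cui1 only in the C1->D1 row
        assert related_concepts(C1, tiny_kb, config) == {D1}

    def test_rel_whitelist_filters_labels(self, tiny_kb):
        config = MappingConfig(rel_whitelist=frozenset({"PAR"}),
                               use_mrcoc=False)
        assert related_concepts(G1, tiny_kb, config) == frozenset()


class TestSemanticFilter:
    def test_empty_allowed_set_gives_empty(self, tiny_kb):
        assert filter_by_semantic_type({G1, C1}, tiny_kb, frozenset()) == frozenset()

    def test_picks_exactly_matching_cuis(self, tiny_kb):
        cuis = {G1, G2, C1, D1, D2}
        out = filter_by_semantic_type(cuis, tiny_kb, frozenset({"T047"}))
        assert out == {D1, D2}

    def test_multi_typed_cui_passes_either_filter(self, tiny_kb):
        assert filter_by_semantic_type({D1}, tiny_kb, frozenset({"T191"})) == {D1}
        assert filter_by_semantic_type({D1}, tiny_kb, frozenset({"T047"})) == {D1}


class TestDirectMap:
    def test_mini_fixture_exact_pair(self, tiny_kb):
        g = ConceptSet("G", (f"CUI:{G1}",))
        c = ConceptSet("C", (f"CUI:{C1}", f"CUI:{C2}"))
        relations = direct_map(g, c, tiny_kb)
        assert [(r.genomic_cui, r.clinical_cui) for r in relations] == [(G1, C1)]
        assert relations[0].direction == "genomic_to_clinic"
        assert relations[0].evidence == (f"MRREL:{G1}:RO:{C1}",)

    def test_empty_relation_tables_give_empty_output(self, tiny_tables):
        kb = build_kb(mrconso=tiny_tables["mrconso"],
                      mrsty=tiny_tables["mrsty"])
        g = ConceptSet("G", ("gene alpha", "gene beta"))
        c = ConceptSet("C", ("abdominal pain", "blood glucose"))
        assert direct_map(g, c, kb) == []

    def test_roles_must_be_g_and_c(self, tiny_kb):
        with pytest.raises(ValueError, match="'G'.*'C'|'C'.*'G'"):
            direct_map(ConceptSet("G", ()), ConceptSet("disease", ()), tiny_kb)

    def test_unresolvable_sources_are_skipped_with_warning(self, tiny_kb, caplog):
        g = ConceptSet("G", ("gene alpha", "missing gene"))
        c = ConceptSet("C", (f"CUI:{C1}",))
        with caplog.at_level("WARNING"):
            relations = direct_map(g, c, tiny_kb)
        assert [(r.genomic_cui, r.clinical_cui) for r in relations] == [(G1, C1)]
        assert "missing gene" in caplog.text

    def test_mirrored_relation_store_gives_mirror_image_maps(self):
        """With every relation stored in both orientations, G->C and C->G
        find the same pairs with opposite directions."""
        tables = _symmetric_tables()
        kb = build_kb(**tables)
        g = ConceptSet("G", (f"CUI:{G1}",))
        c = ConceptSet("C", (f"CUI:{C1}", f"CUI:{C2}"))
        config = MappingConfig(treat_relations_as_bidirectional=False)
        forward = direct_map(g, c, kb, config)
        backward = direct_map(c, g, kb, config)
        assert ({(r.genomic_cui, r.clinical_cui) for r in forward}
                == {(r.genomic_cui, r.clinical_cui) for r in backward})
        assert {r.direction for r in forward} == {"genomic_to_clinic"}
        assert {r.direction for r in backward} == {"clinic_to_genomic"}


def _symmetric_tables():
    from conftest import _atoms, _semantic_types
    relations = []
    for a, b in ((G1, C1), (G1, C2)):
        relations.append(ConceptRelation.make(a, "RO", b))
        relations.append(ConceptRelation.make(b, "RO", a))
    return {"mrconso": _atoms(), "mrrel": relations, "mrcoc": [],
            "mrsty": _semantic_types()}


class TestDiseasesFor:
    def test_cooccurrence_only_disease_neighbourhood(self, tiny_kb):
        assert diseases_for(C2, tiny_kb,
                            MappingConfig(use_mrrel=False)) == {D2}

    def test_cui_without_neighbours_has_no_diseases(self, tiny_kb):
        assert diseases_for(G2, tiny_kb) == frozenset()

    def test_only_disease_typed_neighbours(self, tiny_kb):
        # G1 neighbours: C1 (T184), D1, D2 (T047), X1 (T109)
        assert diseases_for(G1, tiny_kb) == {D1, D2}

    def test_threshold_drops_cooccurrence_only_disease(self, tiny_kb):
        assert diseases_for(G1, tiny_kb,
                            MappingConfig(min_cooccurrence_frequency=2)) == {D1}

    def test_requires_disease_tuis(self, tiny_kb):
        with pytest.raises(ValueError, match="disease_tuis"):
            diseases_for(G1, tiny_kb, MappingConfig(disease_tuis=frozenset()))


class TestIndirectMap:
    def test_shared_crc_disease_yields_relation(self, tiny_kb):
        """g1 and c1 share CRC-flagged d1; g1 and c2 share only d2 (not CRC)."""
        g = ConceptSet("G", (f"CUI:{G1}",))
        c = ConceptSet("C", (f"CUI:{C1}", f"CUI:{C2}"))
        relations = indirect_map(g, c, tiny_kb)
        assert len(relations) == 1
        (rel,) = relations
        assert (rel.genomic_cui, rel.clinical_cui) == (G1, C1)
        assert rel.method == "indirect"
        assert rel.direction == "undirected"
        assert rel.evidence == (D1,)

    def test_empty_crc_set_yields_nothing(self, tiny_kb):
        config = MappingConfig(crc_disease_cuis=frozenset())
        g = ConceptSet("G", (f"CUI:{G1}",))
        c = ConceptSet("C", (f"CUI:{C1}",))
        assert indirect_map(g, c, tiny_kb, config) == []

    def test_explicit_crc_cui_list_overrides_keywords(self, tiny_kb):
        config = MappingConfig(crc_disease_cuis=frozenset({D2}))
        g = ConceptSet("G", (f"CUI:{G1}",))
        c = ConceptSet("C", (f"CUI:{C1}", f"CUI:{C2}"))
        relations = indirect_map(g, c, tiny_kb, config)
        assert {(r.genomic_cui, r.clinical_cui) for r in relations} == {(G1, C2)}

    def test_shrinking_crc_set_never_adds_relations(self, tiny_kb):
        g = ConceptSet("G", (f"CUI:{G1}", f"CUI:{G2}"))
        c = ConceptSet("C", (f"CUI:{C1}", f"CUI:{C2}"))
        full = frozenset({D1, D2})
        pairs_full = {
            (r.genomic_cui, r.clinical_cui)
            for r in indirect_map(g, c, tiny_kb,
                                  MappingConfig(crc_disease_cuis=full))}
        for subset in (frozenset({D1}), frozenset({D2}), frozenset()):
            pairs = {
                (r.genomic_cui, r.clinical_cui)
                for r in indirect_map(g, c, tiny_kb,
                                      MappingConfig(crc_disease_cuis=subset))}
            assert pairs <= pairs_full


class TestCombineCandidates:
    REL_D = CandidateRelation(G1, C1, "direct", "genomic_to_clinic", ("e1",))
    REL_I = CandidateRelation(G1, C1, "indirect", "undirected", (D1,))

    def test_both_empty(self):
        assert combine_candidates([], []) == []

    def test_concatenation_keeps_method_overlap(self):
        assert len(combine_candidates([self.REL_D], [self.REL_I])) == 2

    def test_dedup_merges_methods_and_evidence(self):
        (merged,) = combine_candidates([self.REL_D], [self.REL_I], dedup=True)
        assert merged.method == "direct+indirect"
        assert merged.direction == "genomic_to_clinic"
        assert merged.evidence == (D1, "e1")

    def test_dedup_is_idempotent(self):
        once = combine_candidates([self.REL_D, self.REL_I], [], dedup=True)
        twice = combine_candidates(once, [], dedup=True)
        assert once == twice

    def test_conflicting_directions_collapse_to_undirected(self):
        other = CandidateRelation(G1, C1, "direct", "clinic_to_genomic", ("e2",))
        (merged,) = combine_candidates([self.REL_D, other], [], dedup=True)
        assert merged.direction == "undirected"


class TestConfigAndSerialization:
    def test_config_rejects_no_sources(self):
        with pytest.raises(ValueError, match="use_mrrel"):
            MappingConfig(use_mrrel=False, use_mrcoc=False)

    def test_config_rejects_bad_threshold(self):
        with pytest.raises(ValueError, match="min_cooccurrence_frequency"):
            MappingConfig(min_cooccurrence_frequency=0)

    def test_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "config.yaml"
        path.write_text("min_cooccurrence_frequency: 3\n"
                        "treat_relations_as_bidirectional: false\n",
                        encoding="utf-8")
        config = MappingConfig.from_yaml(path)
        assert config.min_cooccurrence_frequency == 3
        assert not config.treat_relations_as_bidirectional

    def test_yaml_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "config.yaml"
        path.write_text("not_a_key: 1\n", encoding="utf-8")
        with pytest.raises(ValueError, match="not_a_key"):
            MappingConfig.from_yaml(path)

    def test_relation_tsv_roundtrip_and_determinism(self, tiny_kb, tmp_path):
        g = ConceptSet("G", (f"CUI:{G1}",))
        c = ConceptSet("C", (f"CUI:{C1}", f"CUI:{C2}"))
        relations = combine_candidates(direct_map(g, c, tiny_kb),
                                       indirect_map(g, c, tiny_kb))
        first, second = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_relations_tsv(relations, first, tiny_kb, provenance=("p",))
        write_relations_tsv(relations, second, tiny_kb, provenance=("p",))
        assert first.read_bytes() == second.read_bytes()
        assert read_relations_tsv(first) == list(relations)
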