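import itertools

import numpy as np
import pytest


from conftest import make_grid_doc
from _oracles import brute_consensus, random_nonoverlapping_spans

from deidgold.consensus_auto import (
    OverlapCluster,
    ResolutionPolicy,
    build_automatic_consensus,
    cluster_annotations,
    resolve_label,
    resolve_span,
)
from deidgold.corpus_model import (
    Annotation,
    AnnotationSet,
    AnnotationStudy,
    LabelCatalog,
)

CATALOG3 = LabelCatalog(
    labels=frozenset({"First_Name", "Clinician_First_Name", "Town"}),
    parent={"Clinician_First_Name": "First_Name"},
)
POLICY3 = ResolutionPolicy(catalog=CATALOG3)


def study_from_char_spans(*span_lists):
    doc = make_grid_doc("d0", 20)
    sets = []
    for i, spans in enumerate(span_lists):
        src = f"a{i + 1}"
        sets.append(AnnotationSet(
            src, [Annotation("d0", s, e, lab, src) for s, e, lab in spans]))
    return AnnotationStudy(documents=[doc], annotator_sets=sets)


class TestClustering:
    def test_identical_annotations_form_one_cluster(self):
        study = study_from_char_spans([(0, 5, "Town")], [(0, 5, "Town")],
                                      [(0, 5, "Town")])
        clusters = cluster_annotations(study)
        assert len(clusters) == 1
        assert len(clusters[0].members) == 3

    def test_transitive_chaining(self):
        """Spans (0,5),(4,9),(8,12) chain into a single cluster even though
        the first and last do not touch."""
        study = study_from_char_spans([(0, 5, "Town")], [(4, 9, "Town")],
                                      [(8, 12, "Town")])
        clusters = cluster_annotations(study)
        assert len(clusters) == 1

    def test_disjoint_spans_are_singletons(self):
        study = study_from_char_spans([(0, 3, "Town")], [(5, 8, "Town")],
                                      [(10, 13, "Town")])
        assert len(cluster_annotations(study)) == 3

    def test_every_annotation_lands_in_exactly_one_cluster(self, rng):
        study = _random_study(rng)
        clusters = cluster_annotations(study)
        pooled = sorted(a for s in study.annotator_sets for a in s)
        clustered = sorted(m for c in clusters for m in c.members)
        assert pooled == clustered


class TestResolution:
    def test_longest_span_wins(self):
        c = OverlapCluster("d", [Annotation("d", 0, 5, "Town", "a1"),
                                 Annotation("d", 0, 9, "Town", "a2")])
        assert resolve_span(c) == (0, 9)

    def test_singleton_resolves_to_itself(self):
        c = OverlapCluster("d", [Annotation("d", 3, 7, "Town", "a1")])
        assert resolve_span(c) == (3, 7)

    def test_equal_length_tie_takes_smallest_start(self):
        c = OverlapCluster("d", [Annotation("d", 2, 6, "Town", "a1"),
                                 Annotation("d", 0, 4, "Town", "a2")])
        assert resolve_span(c) == (0, 4)

    def test_majority_label_wins(self):
        c = OverlapCluster("d", [
            Annotation("d", 0, 4, "First_Name", "a1"),
            Annotation("d", 0, 4, "First_Name", "a2"),
            Annotation("d", 0, 4, "Town", "a3")])
        assert resolve_label(c, POLICY3) == "First_Name"

    def test_specificity_beats_two_way_tie(self):
        """First_Name vs Clinician_First_Name resolves to the more
        specific Clinician_First_Name."""
        c = OverlapCluster("d", [
            Annotation("d", 0, 4, "First_Name", "a1"),
            Annotation("d", 0, 4, "Clinician_First_Name", "a2")])
        assert resolve_label(c, POLICY3) == "Clinician_First_Name"

    def test_incomparable_tie_falls_back_to_label_order(self):
        c = OverlapCluster("d", [
            Annotation("d", 0, 4, "Town", "a1"),
            Annotation("d", 0, 4, "First_Name", "a2")])
        assert resolve_label(c, POLICY3) == "First_Name"  # lexicographic

    def test_label_outside_catalog_is_an_error(self):
        c = OverlapCluster("d", [Annotation("d", 0, 4, "Nope", "a1")])
        with pytest.raises(ValueError, match="catalog"):
            resolve_label(c, POLICY3)


class TestBuildConsensus:
    def test_idempotence_on_unanimous_study(self):
        spans = [(0, 4, "Town"), (8, 14, "First_Name")]
        study = study_from_char_spans(spans, spans, spans)
        cons = build_automatic_consensus(study, POLICY3)
        assert [(a.start, a.end, a.label) for a in cons] == spans

    def test_disjoint_annotators_give_exact_union(self):
        study = study_from_char_spans([(0, 3, "Town")], [(5, 8, "Town")],
                                      [(10, 14, "First_Name")])
        cons = build_automatic_consensus(study, POLICY3)
        assert len(cons) == 3

    def test_singletons_included_by_default_and_excludable(self):
        study = study_from_char_spans([(0, 3, "Town"), (5, 8, "Town")],
                                      [(0, 3, "Town")])
        assert len(build_automatic_consensus(study, POLICY3)) == 2
        no_single = build_automatic_consensus(
            study, ResolutionPolicy(catalog=CATALOG3,
                                    include_singletons=False))
        assert [(a.start, a.end) for a in no_single] == [(0, 3)]

    def test_coverage_every_input_intersects_consensus(self, rng):
        """Recall orientation: within every mutually-overlapping cluster
        the resolved span touches each member, so no annotator's judgment
        disappears.  (A transitively *chained* cluster resolves to its
        single longest member span, which by construction cannot reach a
        chain's far end — the one principled exception.)"""
        for _ in range(20):
            study = _random_study(rng)
            cons = build_automatic_consensus(study, POLICY3)
            for cluster in cluster_annotations(study):
                pairwise = all(
                    x.overlaps(y) for x, y in
                    itertools.combinations(cluster.members, 2))
                if pairwise:
                    for m in cluster.members:
                        assert any(m.overlaps(c) for c in cons)

    def test_unanimous_pairs_survive_verbatim(self, rng):
        for _ in range(20):
            study = _random_study(rng)
            cons = build_automatic_consensus(study, POLICY3)
            keys = {(a.start, a.end) for a in cons}
            span_sets = [
                {(a.start, a.end, a.label) for a in s}
                for s in study.annotator_sets
            ]
            for x, y in itertools.combinations(span_sets, 2):
                for s, e, lab in x & y:
                    # identical in >=2 sets and in no overlapping conflict
                    cluster = [c for c in cluster_annotations(study)
                               if any(m.span == (s, e) for m in c.members)]
                    if all(m.span == (s, e) for m in cluster[0].members):
                        assert (s, e) in keys

    def test_count_equals_cluster_count(self, rng):
        study = _random_study(rng)
        cons = build_automatic_consensus(study, POLICY3)
        assert len(cons) == len(cluster_annotations(study))


def _random_study(rng, n_tokens: int = 20):
    labels = ("First_Name", "Clinician_First_Name", "Town")
    lists = [random_nonoverlapping_spans(rng, n_tokens, 5, labels)
             for _ in range(3)]
    # retry degenerate all-empty draws so the study is never trivial
    if not any(lists):
        lists[0] = [(0, 3, "Town")]
    return study_from_char_spans(*lists)


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_studies(self, rng):
        """The consensus builder agrees with an independent brute-force
        implementation of union + majority + longest-span + specificity +
        singleton inclusion on hundreds of random 3-annotator studies."""
        for _ in range(300):
            study = _random_study(rng)
            cons = build_automatic_consensus(study, POLICY3)
            got = sorted((a.doc_id, a.start, a.end, a.label) for a in cons)
            by_src = {
                s.source: [(a.doc_id, a.start, a.end, a.label) for a in s]
                for s in study.annotator_sets
            }
            assert got == brute_consensus(by_src, CATALOG3)

    def test_matches_brute_force_without_singletons(self, rng):
        policy = ResolutionPolicy(catalog=CATALOG3, include_singletons=False)
        for _ in range(100):
            study = _random_study(rng)
            cons = build_automatic_consensus(study, policy)
            got = sorted((a.doc_id, a.start, a.end, a.label) for a in cons)
            by_src = {
                s.source: [(a.doc_id, a.start, a.end, a.label) for a in s]
                for s in study.annotator_sets
            }
            assert got == brute_consensus(by_src, CATALOG3,
                                          include_singletons=False)
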