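import pytest

from conftest import make_grid_doc
from _oracles import optimal_relevant, random_nonoverlapping_spans

from deidgold.corpus_model import Annotation, AnnotationSet, Document
from deidgold.class_schemes import ClassScheme, apply_scheme
from deidgold.evaluation import (
    ClassCounts,
    compute_prf,
    count_matches,
    fp_audit,
    per_class_report,
)

LABELS = ("Town", "First_Name", "Age")


def aset(source, spans):
    return AnnotationSet(
        source, [Annotation("d0", s, e, lab, source) for s, e, lab in spans])


def random_pair(rng, n_tokens=18, max_n=6):
    g = aset("gold", random_nonoverlapping_spans(rng, n_tokens, max_n, LABELS))
    p = aset("pred", random_nonoverlapping_spans(rng, n_tokens, max_n, LABELS))
    return g, p


class TestCountMatches:
    def test_perfect_prediction(self):
        g = aset("g", [(0, 4, "Town"), (8, 12, "Age")])
        p = aset("p", [(0, 4, "Town"), (8, 12, "Age")])
        for mode in ("exact", "partial"):
            c = count_matches(g, p, mode).overall
            assert (c.annotated, c.retrieved, c.relevant) == (2, 2, 2)

    def test_partial_credits_overlap_that_exact_rejects(self):
        g = aset("g", [(0, 9, "Town")])
        p = aset("p", [(0, 5, "Town")])
        assert count_matches(g, p, "exact").overall.relevant == 0
        assert count_matches(g, p, "partial").overall.relevant == 1

    def test_label_must_match_in_both_modes(self):
        g = aset("g", [(0, 9, "Town")])
        p = aset("p", [(0, 9, "Age")])
        for mode in ("exact", "partial"):
            assert count_matches(g, p, mode).overall.relevant == 0

    def test_exact_is_token_level_when_docs_given(self):
        """Spans that differ only inside a token boundary count as exact
        matches once snapped to tokens."""
        doc = Document("d0", "en 34-årig man")
        g = AnnotationSet("g", [Annotation("d0", 3, 10, "Age")])
        p = AnnotationSet("p", [Annotation("d0", 3, 5, "Age")])
        assert count_matches(g, p, "exact").overall.relevant == 0
        assert count_matches(g, p, "exact", [doc]).overall.relevant == 1

    def test_one_to_one_never_double_credits(self):
        g = aset("g", [(0, 10, "Town")])
        p = aset("p", [(0, 4, "Town"), (6, 10, "Town")])
        c = count_matches(g, p, "partial").overall
        assert c.relevant == 1

    def test_unknown_mode_rejected(self):
        g = aset("g", [(0, 4, "Town")])
        with pytest.raises(ValueError):
            count_matches(g, g, "fuzzy")

    def test_matches_optimal_bipartite_matching_on_random_pairs(self, rng):
        """Greedy one-to-one matching attains the maximum matching on
        1,000 seeded random gold/prediction pairs in both modes."""
        for _ in range(1000):
            g, p = random_pair(rng)
            gt = [(a.doc_id, a.start, a.end, a.label) for a in g]
            pt = [(a.doc_id, a.start, a.end, a.label) for a in p]
            for mode in ("exact", "partial"):
                got = count_matches(g, p, mode).overall.relevant
                assert got == optimal_relevant(gt, pt, mode)

    def test_relevant_is_symmetric(self, rng):
        for _ in range(200):
            g, p = random_pair(rng)
            for mode in ("exact", "partial"):
                assert count_matches(g, p, mode).overall.relevant == \
                    count_matches(p, g, mode).overall.relevant

    def test_partial_dominates_exact(self, rng):
        for _ in range(200):
            g, p = random_pair(rng)
            ex = count_matches(g, p, "exact").overall
            pa = count_matches(g, p, "partial").overall
            assert pa.relevant >= ex.relevant
            for attr in ("precision", "recall", "f_score"):
                assert getattr(compute_prf(pa), attr) >= \
                    getattr(compute_prf(ex), attr)


class TestPRF:
    @pytest.mark.parametrize("counts,expected", [
        (ClassCounts(2, 2, 2), (1.0, 1.0, 1.0)),
        (ClassCounts(2, 2, 1), (0.5, 0.5, 0.5)),
        (ClassCounts(2, 1, 1), (1.0, 0.5, 2 / 3)),
    ])
    def test_closed_forms(self, counts, expected):
        prf = compute_prf(counts)
        assert (prf.precision, prf.recall, prf.f_score) == \
            pytest.approx(expected)

    def test_zero_denominators_flagged(self):
        prf = compute_prf(ClassCounts(annotated=3, retrieved=0, relevant=0))
        assert prf.precision == 0.0 and not prf.precision_defined
        assert prf.recall_defined

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ClassCounts(annotated=1, retrieved=1, relevant=2)


class TestReport:
    def test_single_class_row_equals_micro(self):
        g = aset("g", [(0, 4, "Town"), (8, 12, "Town")])
        p = aset("p", [(0, 4, "Town")])
        frame = per_class_report(g, p).to_frame()
        assert frame.loc["Town", "exact_f"] == \
            frame.loc["__micro__", "exact_f"] == pytest.approx(2 / 3)

    def test_no_predictions_means_zero_retrieved(self):
        g = aset("g", [(0, 4, "Town")])
        frame = per_class_report(g, AnnotationSet("p")).to_frame()
        assert frame.loc["__micro__", "retrieved"] == 0

    def test_micro_equals_pooled_counts_on_random_pairs(self, rng):
        for _ in range(100):
            g, p = random_pair(rng)
            rep = per_class_report(g, p)
            pooled = rep.exact.overall
            by_hand = ClassCounts(
                annotated=sum(c.annotated for c in rep.exact.per_class.values()),
                retrieved=sum(c.retrieved for c in rep.exact.per_class.values()),
                relevant=sum(c.relevant for c in rep.exact.per_class.values()),
            )
            assert pooled == by_hand


class TestSchemeCoarsening:
    def test_merging_labels_never_decreases_relevant(self, rng):
        """Applying the same non-deleting scheme to gold and prediction
        can only create new matches, never destroy one."""
        scheme = ClassScheme("pool_names",
                             {"Town": "Place", "First_Name": "Name",
                              "Age": "Name"})
        for _ in range(300):
            g, p = random_pair(rng)
            for mode in ("exact", "partial"):
                before = count_matches(g, p, mode).overall.relevant
                after = count_matches(apply_scheme(g, scheme),
                                      apply_scheme(p, scheme),
                                      mode).overall.relevant
                assert after >= before


class TestFpAudit:
    def test_perfect_prediction_gives_empty_audit(self):
        doc = make_grid_doc("d0", 18)
        g = aset("g", [(0, 7, "Town")])
        assert fp_audit(g, g, [doc]) == []

    def test_one_spurious_prediction_one_row_with_context(self):
        doc = make_grid_doc("d0", 18)
        g = aset("g", [(0, 7, "Town")])
        p = aset("p", [(0, 7, "Town"), (20, 27, "Age")])
        rows = fp_audit(g, p, [doc])
        assert len(rows) == 1
        assert rows[0]["surface"] == doc.text[20:27]
        assert rows[0]["surface"] in rows[0]["context"]

    def test_length_equals_retrieved_minus_relevant(self, rng):
        doc = make_grid_doc("d0", 18)
        for _ in range(200):
            g, p = random_pair(rng)
            c = count_matches(g, p, "exact", [doc]).overall
            assert len(fp_audit(g, p, [doc])) == c.retrieved - c.relevant
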