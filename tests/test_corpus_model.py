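import pytest

from deidgold.corpus_model import (
    Annotation,
    AnnotationSet,
    Document,
    StandoffError,
    decode_bio,
    encode_bio,
    read_conll,
    read_standoff,
    snap_to_tokens,
    tokenize,
    write_conll,
    write_standoff,
)


# Hand-tokenized fixtures written down before the tokenizer existed.
HAND_TOKENIZED = [
    ("", []),
    ("34-årig man", ["34-årig", "man"]),
    ("Karolinska Univ. Sjukh, Huddinge",
     ["Karolinska", "Univ.", "Sjukh", ",", "Huddinge"]),
    ("Avd. 11 på Karolinska", ["Avd.", "11", "på", "Karolinska"]),
    ("inkommer 3/5 kl. 14:30.", ["inkommer", "3/5", "kl.", "14:30", "."]),
    ("tel 08-123 456 78", ["tel", "08-123", "456", "78"]),
    ("S:t Eriksgårdens vårdcentral", ["S:t", "Eriksgårdens", "vårdcentral"]),
    ("Storgatan 1, 114 44 Solvik", ["Storgatan", "1", ",", "114", "44", "Solvik"]),
]


@pytest.mark.parametrize("text,expected", HAND_TOKENIZED,
                         ids=[repr(t) for t, _ in HAND_TOKENIZED])
def test_tokenize_matches_hand_tokenization(text, expected):
    spans = tokenize(text)
    assert [text[s:e] for s, e in spans] == expected


def test_tokenize_offsets_are_consistent(rng):
    """Token substrings are non-empty, whitespace-free, strictly ordered,
    and skipped separators are whitespace only."""
    words = ["Anna", "34-årig", "(", "Univ.", "08-123", "b", "...", "år"]
    for _ in range(50):
        n = rng.integers(0, 10)
        text = " ".join(str(words[i]) for i in rng.integers(0, len(words), n))
        spans = tokenize(text)
        prev = 0
        for s, e in spans:
            assert prev <= s < e <= len(text)
            assert text[s:e].strip() == text[s:e] != ""
            assert text[prev:s].strip() == ""
            prev = e


def test_document_rejects_bad_token_spans():
    with pytest.raises(ValueError):
        Document("d", "ab cd", tokens=[(0, 4)])  # contains whitespace
    with pytest.raises(ValueError):
        Document("d", "ab cd", tokens=[(0, 2), (1, 4)])  # overlap


def test_annotation_set_rejects_overlap_and_duplicates():
    a1 = Annotation("d", 0, 5, "X")
    with pytest.raises(ValueError):
        AnnotationSet("s", [a1, Annotation("d", 3, 8, "Y")])
    with pytest.raises(ValueError):
        AnnotationSet("s", [a1, Annotation("d", 0, 5, "X")])


class TestStandoff:
    def test_single_record(self, tmp_path):
        (tmp_path / "d.txt").write_text("Anna kommer", encoding="utf-8")
        (tmp_path / "d.ann").write_text("T1\tFirst_Name 0 4\tAnna\n",
                                        encoding="utf-8")
        doc, aset = read_standoff(tmp_path / "d.ann", tmp_path / "d.txt")
        assert [(a.start, a.end, a.label) for a in aset] == \
            [(0, 4, "First_Name")]

    def test_surface_mismatch_is_an_integrity_error(self, tmp_path):
        (tmp_path / "d.txt").write_text("Anna kommer", encoding="utf-8")
        (tmp_path / "d.ann").write_text("T1\tFirst_Name 0 4\tBnna\n",
                                        encoding="utf-8")
        with pytest.raises(StandoffError, match="surface"):
            read_standoff(tmp_path / "d.ann", tmp_path / "d.txt")

    def test_out_of_range_offsets_name_the_line(self, tmp_path):
        (tmp_path / "d.txt").write_text("kort", encoding="utf-8")
        (tmp_path / "d.ann").write_text("T1\tX 0 99\tkort\n", encoding="utf-8")
        with pytest.raises(StandoffError, match=":1"):
            read_standoff(tmp_path / "d.ann", tmp_path / "d.txt")

    def test_round_trip_identity_on_random_sets(self, tmp_path, rng):
        from deidgold.synthetic_data import SynthConfig, generate_gold_corpus

        docs, gold = generate_gold_corpus(
            SynthConfig(n_documents=8, tokens_per_doc=60, seed=3))
        for doc in docs:
            write_standoff(gold, doc, tmp_path / f"{doc.doc_id}.ann",
                           tmp_path / f"{doc.doc_id}.txt")
            _, back = read_standoff(tmp_path / f"{doc.doc_id}.ann",
                                    tmp_path / f"{doc.doc_id}.txt",
                                    source="gold", doc_id=doc.doc_id)
            assert [(a.start, a.end, a.label) for a in back] == \
                [(a.start, a.end, a.label) for a in gold.for_doc(doc.doc_id)]

    def test_empty_set_writes_empty_file(self, tmp_path):
        doc = Document("d", "text här")
        write_standoff(AnnotationSet("s"), doc, tmp_path / "d.ann")
        assert (tmp_path / "d.ann").read_text() == ""


class TestBIO:
    def test_no_annotations_is_all_outside(self, grid_doc):
        pairs = encode_bio(grid_doc, [])
        assert {tag for _, tag in pairs} == {"O"}

    def test_single_span_gets_b_tag(self):
        doc = Document("d", "Anna Svensson kommer")
        pairs = encode_bio(doc, [Annotation("d", 5, 13, "Last_Name")])
        assert [t for _, t in pairs] == ["O", "B-Last_Name", "O"]

    def test_multi_token_span_is_b_then_i(self):
        doc = Document("d", "på Norrbacka sjukhus idag")
        pairs = encode_bio(doc, [Annotation("d", 3, 20, "Health_Care_Unit")])
        assert [t for _, t in pairs] == \
            ["O", "B-Health_Care_Unit", "I-Health_Care_Unit", "O"]

    def test_subtoken_span_covers_whole_token(self):
        """A span on the digits inside '34-årig' tags (and decodes to) the
        entire hyphenated token — sub-tokenization is never emitted."""
        doc = Document("d", "en 34-årig man")
        pairs = encode_bio(doc, [Annotation("d", 3, 5, "Age")])
        assert [t for _, t in pairs] == ["O", "B-Age", "O"]
        decoded = decode_bio(doc, [t for _, t in pairs], "x")
        (ann,) = decoded.annotations
        assert doc.text[ann.start:ann.end] == "34-årig"

    def test_overlapping_annotations_are_rejected(self, grid_doc):
        anns = [Annotation("d0", 0, 6, "X"), Annotation("d0", 4, 10, "Y")]
        with pytest.raises(ValueError):
            encode_bio(grid_doc, anns)

    def test_orphan_inside_tag_is_repaired_to_begin(self, grid_doc):
        aset = decode_bio(grid_doc, ["O", "I-Age"] + ["O"] * 10, "x")
        (ann,) = aset.annotations
        assert (ann.start, ann.end, ann.label) == (4, 7, "Age")

    def test_unknown_tag_raises(self, grid_doc):
        with pytest.raises(ValueError, match="unknown"):
            decode_bio(grid_doc, ["Q-Age"] + ["O"] * 11, "x")

    def test_round_trip_on_random_token_aligned_sets(self, rng):
        """decode(encode(s)) == s for seeded random non-overlapping,
        token-aligned annotation sets."""
        from _oracles import random_nonoverlapping_spans
        from conftest import make_grid_doc

        labels = ("Age", "Town", "First_Name")
        for trial in range(100):
            gdoc = make_grid_doc("d", 15)
            spans = random_nonoverlapping_spans(rng, 15, 5, labels)
            anns = [Annotation("d", s, e, lab) for s, e, lab in spans]
            pairs = encode_bio(gdoc, anns)
            back = decode_bio(gdoc, [t for _, t in pairs], "x")
            assert [(a.start, a.end, a.label) for a in back] == \
                sorted((s, e, l) for s, e, l in spans)


def test_snap_to_tokens_extends_outward():
    doc = Document("d", "en 34-årig man")
    snapped = snap_to_tokens(Annotation("d", 3, 5, "Age"), doc)
    assert doc.text[snapped.start:snapped.end] == "34-årig"
    aligned = Annotation("d", 3, 10, "Age")
    assert snap_to_tokens(aligned, doc) == aligned


def test_conll_round_trip(tmp_path):
    tagged = {"a": [("Anna", "B-First_Name"), (".", "O")],
              "b": [("hem", "O")]}
    write_conll(tmp_path / "x.conll", tagged)
    assert read_conll(tmp_path / "x.conll") == tagged
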