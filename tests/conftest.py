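from __future__ import annotations

import numpy as np
import pytest

from deidgold.corpus_model import (
    Annotation,
    AnnotationSet,
    AnnotationStudy,
    Document,
)


def make_grid_doc(doc_id: str = "d0", n_tokens: int = 12,
                  token_len: int = 4) -> Document:
    """A document of ``n_tokens`` identical-width tokens on a regular
    character grid: token i covers [i*token_len, i*token_len+token_len-1),
    followed by one space."""
    words = [f"t{i:02d}".ljust(token_len - 1, "x") for i in range(n_tokens)]
    return Document(doc_id, " ".join(words))


def grid_ann(doc_id: str, tok_start: int, tok_end: int, label: str,
             source: str = "", token_len: int = 4) -> Annotation:
    """Annotation covering tokens [tok_start, tok_end) of a grid doc."""
    return Annotation(doc_id, tok_start * token_len,
                      tok_end * token_len - 1, label, source)


@pytest.fixture
def grid_doc() -> Document:
    return make_grid_doc()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_study(doc: Document, *span_lists,
               sources=None) -> AnnotationStudy:
    """Build a study over one grid document from per-annotator lists of
    (tok_start, tok_end, label) triples."""
    sources = sources or [f"a{i + 1}" for i in range(len(span_lists))]
    sets = [
        AnnotationSet(src, [grid_ann(doc.doc_id, s, e, lab, src)
                            for s, e, lab in spans])
        for src, spans in zip(sources, span_lists)
    ]
    return AnnotationStudy(documents=[doc], annotator_sets=sets)


@pytest.fixture
def small_synth_study():
    from deidgold.synthetic_data import SynthConfig, build_annotation_study

    cfg = SynthConfig(n_documents=20, tokens_per_doc=120, seed=7)
    return build_annotation_study(cfg)
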