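"""Core data types and text plumbing for PHI span annotation.

Everything downstream (consensus building, agreement statistics, the CRF
de-identifier, evaluation) operates on the types defined here:

* :class:`Document` — plain text plus a deterministic tokenization.
* :class:`Annotation` — one labeled character span from one source
  (a human annotator, a consensus procedure, or a system).
* :class:`AnnotationSet` — one source's flat (non-nested) annotations.
* :class:`LabelCatalog` — the PHI label inventory with its
  generic-to-specific refinement order (e.g. ``First_Name`` is refined by
  ``Clinician_First_Name``).

Offsets are 0-based, half-open, character-level everywhere; readers convert
on ingest.  Annotation interchange uses BRAT-style standoff (``.ann`` +
``.txt``) and CoNLL-style two-column token/tag files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "Annotation",
    "AnnotationSet",
    "Document",
    "LabelCatalog",
    "DEFAULT_CATALOG",
    "tokenize",
    "read_standoff",
    "write_standoff",
    "read_corpus_dir",
    "write_corpus_dir",
    "encode_bio",
    "decode_bio",
    "snap_to_tokens",
    "write_conll",
    "read_conll",
]


# ---------------------------------------------------------------------------
# Annotations and documents
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Annotation:
    """One labeled character span: ``text[start:end]`` carries PHI class
    ``label`` according to ``source``.

    Offsets are 0-based half-open.  Ordering is lexicographic on
    ``(doc_id, start, end, label, source)``, which gives every writer a
    deterministic output order.
    """

    doc_id: str
    start: int
    end: int
    label: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid span ({self.start}, {self.end}) in doc {self.doc_id!r}"
            )

    def overlaps(self, other: "Annotation") -> bool:
        return (
            self.doc_id == other.doc_id
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


class Document:
    """A plain-text record with its token spans.

    Tokenization is computed once, lazily, by :func:`tokenize`; token spans
    are non-overlapping, strictly increasing and whitespace-free.
    """

    __slots__ = ("doc_id", "text", "_tokens")

    def __init__(self, doc_id: str, text: str,
                 tokens: Sequence[tuple[int, int]] | None = None) -> None:
        self.doc_id = doc_id
        self.text = text
        self._tokens: list[tuple[int, int]] | None = (
            list(tokens) if tokens is not None else None
        )
        if self._tokens is not None:
            _check_token_spans(self._tokens, text)

    @property
    def tokens(self) -> list[tuple[int, int]]:
        if self._tokens is None:
            self._tokens = tokenize(self.text)
        return self._tokens

    def token_strings(self) -> list[str]:
        return [self.text[s:e] for s, e in self.tokens]

    def __repr__(self) -> str:  # pragma: no cover
        return f"Document({self.doc_id!r}, {len(self.text)} chars)"

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Document)
            and self.doc_id == other.doc_id
            and self.text == other.text
        )

    def __hash__(self) -> int:
        return hash((self.doc_id, self.text))


def _check_token_spans(tokens: Sequence[tuple[int, int]], text: str) -> None:
    prev_end = 0
    for s, e in tokens:
        if not (0 <= s < e <= len(text)):
            raise ValueError(f"token span ({s}, {e}) outside text")
        if s < prev_end:
            raise ValueError("token spans overlap or are unordered")
        if any(ch.isspace() for ch in text[s:e]):
            raise ValueError(f"token {text[s:e]!r} contains whitespace")
        prev_end = e


class AnnotationSet:
    """All annotations produced by one source, flat (non-nested).

    Invariants enforced on construction: no duplicate
    ``(doc_id, start, end, label)`` records, and no two annotations within
    the set overlap each other — the annotation model has no nested classes.
    """

    def __init__(self, source: str,
                 annotations: Iterable[Annotation] = (),
                 check_overlap: bool = True) -> None:
        self.source = source
        anns = sorted(
            replace(a, source=source) if a.source != source else a
            for a in annotations
        )
        seen: set[tuple[str, int, int, str]] = set()
        for a in anns:
            key = (a.doc_id, a.start, a.end, a.label)
            if key in seen:
                raise ValueError(f"duplicate annotation {key} in set {source!r}")
            seen.add(key)
        if check_overlap:
            prev: Annotation | None = None
            for a in anns:
                if prev is not None and a.overlaps(prev):
                    raise ValueError(
                        f"overlapping annotations in set {source!r}: "
                        f"{prev} / {a}"
                    )
                if prev is None or a.doc_id != prev.doc_id or a.end > prev.end:
                    prev = a
        self.annotations: list[Annotation] = anns

    def __len__(self) -> int:
        return len(self.annotations)

    def __iter__(self) -> Iterator[Annotation]:
        return iter(self.annotations)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return [
            (a.doc_id, a.start, a.end, a.label) for a in self.annotations
        ] == [(a.doc_id, a.start, a.end, a.label) for a in other.annotations]

    def __repr__(self) -> str:  # pragma: no cover
        return f"AnnotationSet({self.source!r}, n={len(self)})"

    def for_doc(self, doc_id: str) -> list[Annotation]:
        return [a for a in self.annotations if a.doc_id == doc_id]

    def labels(self) -> set[str]:
        return {a.label for a in self.annotations}

    def doc_ids(self) -> list[str]:
        return sorted({a.doc_id for a in self.annotations})


@dataclass
class AnnotationStudy:
    """A document collection plus per-annotator annotation sets — the unit
    that consensus building and agreement statistics operate on."""

    documents: list[Document]
    annotator_sets: list[AnnotationSet]
    gold: AnnotationSet | None = None

    def __post_init__(self) -> None:
        if len(self.annotator_sets) < 2:
            raise ValueError("a study needs at least two annotators")
        known = {d.doc_id for d in self.documents}
        for aset in self.annotator_sets:
            stray = set(aset.doc_ids()) - known
            if stray:
                raise ValueError(
                    f"annotator {aset.source!r} references unknown docs {stray}"
                )

    @property
    def doc_map(self) -> dict[str, Document]:
        return {d.doc_id: d for d in self.documents}

    def sources(self) -> list[str]:
        return [s.source for s in self.annotator_sets]


# ---------------------------------------------------------------------------
# Label catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabelCatalog:
    """A PHI label inventory plus its refinement (specificity) order.

    ``parent`` maps each specific label to its single generic parent, e.g.
    ``Clinician_First_Name -> First_Name``: an annotation with the specific
    label implies the generic one.  The relation must be acyclic.
    """

    labels: frozenset[str]
    parent: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for child, par in self.parent.items():
            if child not in self.labels or par not in self.labels:
                raise ValueError(f"specificity pair {child}->{par} outside catalog")
        # acyclicity: walking parents must terminate
        for lab in self.parent:
            seen = {lab}
            cur = lab
            while cur in self.parent:
                cur = self.parent[cur]
                if cur in seen:
                    raise ValueError(f"specificity cycle through {lab!r}")
                seen.add(cur)

    def ancestors(self, label: str) -> list[str]:
        out = []
        cur = label
        while cur in self.parent:
            cur = self.parent[cur]
            out.append(cur)
        return out

    def comparable(self, a: str, b: str) -> bool:
        return a == b or b in self.ancestors(a) or a in self.ancestors(b)

    def more_specific(self, a: str, b: str) -> str:
        """Of two comparable labels, the one lower in the refinement order."""
        if a == b:
            return a
        if b in self.ancestors(a):
            return a
        if a in self.ancestors(b):
            return b
        raise ValueError(f"labels {a!r} and {b!r} are not comparable")

    def most_specific(self, labels: Sequence[str]) -> str | None:
        """The unique most-specific label if all are pairwise comparable,
        else None."""
        cur = labels[0]
        for lab in labels[1:]:
            if not self.comparable(cur, lab):
                return None
            cur = self.more_specific(cur, lab)
        # every other label must be an ancestor of (or equal to) cur
        for lab in labels:
            if lab != cur and lab not in self.ancestors(cur):
                return None
        return cur


def _default_catalog() -> LabelCatalog:
    generic = [
        "Age", "First_Name", "Last_Name", "Date_Part", "Full_Date",
        "Location", "Health_Care_Unit", "Phone_Number",
        "E-mail_Address", "Social_Security_Number",
    ]
    refinements = {
        "Clinician_First_Name": "First_Name",
        "Patient_First_Name": "First_Name",
        "Relative_First_Name": "First_Name",
        "Clinician_Last_Name": "Last_Name",
        "Patient_Last_Name": "Last_Name",
        "Relative_Last_Name": "Last_Name",
        "Age_Over_89": "Age",
        "Street_Address": "Location",
        "Town": "Location",
        "Municipality": "Location",
        "Country": "Location",
        "Organization": "Location",
    }
    deprecated = ["Relation", "Ethnicity"]
    labels = frozenset(generic) | frozenset(refinements) | frozenset(deprecated)
    return LabelCatalog(labels=labels, parent=refinements)


#: Default PHI catalog: the proposed post-refinement label set plus the
#: pre-refinement name/age/location subclasses and the two classes the
#: refined guidelines delete.  The original study's full inventory is not
#: published; this catalog covers every label the pipeline's rules mention.
DEFAULT_CATALOG = _default_catalog()


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

def _load_abbreviations() -> frozenset[str]:
    data = resources.files("deidgold.data").joinpath("abbreviations.txt")
    out = set()
    for line in data.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line.lower())
    return frozenset(out)


_ABBREVIATIONS = _load_abbreviations()

# Within a whitespace-delimited chunk, in priority order:
#   1. number-ish runs (dates, phone fragments, ages): digits possibly
#      joined by / : . , - so "3/5", "2007-03-14", "08-123" stay whole;
#   2. words, keeping internal hyphens/colons/apostrophes between
#      alphanumerics so "34-årig" and "S:t" stay whole, with an optional
#      trailing period (validated against the abbreviation list);
#   3. any single non-space character (punctuation).
_TOKEN_RE = re.compile(
    r"""
    \d+(?:[/:.,\-]\d+)+           # joined numeric run (date/phone/ratio)
    | \w+(?:[-:']\w+)*\.?         # word, maybe hyphen/colon joined, maybe trailing .
    | \S                          # any other single character
    """,
    re.UNICODE | re.VERBOSE,
)


def tokenize(text: str) -> list[tuple[int, int]]:
    """Split ``text`` into token character spans.

    Whitespace delimits; punctuation is split off except inside numeric
    runs (dates, phone numbers), hyphen/colon-joined words (``34-årig``,
    ``S:t``) and listed abbreviations with a trailing period (``Univ.``).
    Deterministic; the concatenation of token substrings plus the skipped
    separators reconstructs the input.
    """
    spans: list[tuple[int, int]] = []
    for m in _TOKEN_RE.finditer(text):
        tok = m.group(0)
        start, end = m.start(), m.end()
        if tok.endswith(".") and len(tok) > 1 and not tok[:-1].isdigit():
            # keep the period only for known abbreviations
            if tok[:-1].lower() not in _ABBREVIATIONS:
                spans.append((start, end - 1))
                spans.append((end - 1, end))
                continue
        spans.append((start, end))
    return spans


def snap_to_tokens(ann: Annotation, doc: Document) -> Annotation:
    """Extend ``ann`` outward to enclosing token boundaries.

    Sub-token spans are disallowed by the refined annotation guidelines, so
    a span covering part of a token is widened to cover it whole.  A span
    already aligned (or touching no token) is returned unchanged.
    """
    new_start, new_end = ann.start, ann.end
    for s, e in doc.tokens:
        if s < ann.end and ann.start < e:  # token intersects span
            new_start = min(new_start, s)
            new_end = max(new_end, e)
    if (new_start, new_end) == (ann.start, ann.end):
        return ann
    return replace(ann, start=new_start, end=new_end)


# ---------------------------------------------------------------------------
# Standoff (BRAT-style) I/O
# ---------------------------------------------------------------------------

class StandoffError(ValueError):
    """Raised on malformed or inconsistent standoff input."""


def _parse_ann_line(line: str, lineno: int, path: str):
    parts = line.rstrip("\n").split("\t")
    if len(parts) < 2 or not parts[0].startswith("T"):
        raise StandoffError(f"{path}:{lineno}: not a text-bound line: {line!r}")
    head = parts[1].split(" ")
    if len(head) != 3:
        raise StandoffError(f"{path}:{lineno}: expected 'LABEL start end'")
    label, start_s, end_s = head
    try:
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise StandoffError(f"{path}:{lineno}: non-integer offsets") from exc
    surface = parts[2] if len(parts) > 2 else None
    return label, start, end, surface


def read_standoff(ann_path: str | Path, text_path: str | Path,
                  source: str | None = None,
                  doc_id: str | None = None) -> tuple[Document, AnnotationSet]:
    """Read one ``.txt`` + ``.ann`` standoff pair.

    Every annotation's recorded surface string must equal the text slice at
    its offsets; a mismatch raises :class:`StandoffError` naming the line.
    """
    ann_path, text_path = Path(ann_path), Path(text_path)
    text = text_path.read_text(encoding="utf-8")
    did = doc_id if doc_id is not None else text_path.stem
    src = source if source is not None else ann_path.stem
    doc = Document(did, text)
    anns: list[Annotation] = []
    for lineno, line in enumerate(
            ann_path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        label, start, end, surface = _parse_ann_line(line, lineno, str(ann_path))
        if not (0 <= start < end <= len(text)):
            raise StandoffError(
                f"{ann_path}:{lineno}: offsets ({start}, {end}) outside "
                f"document of length {len(text)}"
            )
        if surface is not None and text[start:end] != surface:
            raise StandoffError(
                f"{ann_path}:{lineno}: surface {surface!r} does not match "
                f"text slice {text[start:end]!r}"
            )
        anns.append(Annotation(did, start, end, label, src))
    return doc, AnnotationSet(src, anns)


def write_standoff(aset: AnnotationSet, doc: Document,
                   ann_path: str | Path,
                   text_path: str | Path | None = None) -> None:
    """Write one document's annotations as a BRAT ``.ann`` file (and
    optionally the ``.txt``).  Deterministic ordering by (start, end, label).
    """
    lines = []
    for i, a in enumerate(sorted(aset.for_doc(doc.doc_id)), start=1):
        surface = doc.text[a.start:a.end]
        lines.append(f"T{i}\t{a.label} {a.start} {a.end}\t{surface}")
    Path(ann_path).write_text(
        "\n".join(lines) + ("\n" if lines else ""), encoding="utf-8"
    )
    if text_path is not None:
        Path(text_path).write_text(doc.text, encoding="utf-8")


def write_corpus_dir(docs: Sequence[Document], asets: Mapping[str, AnnotationSet],
                     out_dir: str | Path) -> None:
    """Write ``<doc_id>.txt`` plus ``<doc_id>.<source>.ann`` per document
    and source, in doc_id order."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for doc in sorted(docs, key=lambda d: d.doc_id):
        (out / f"{doc.doc_id}.txt").write_text(doc.text, encoding="utf-8")
        for name, aset in sorted(asets.items()):
            write_standoff(aset, doc, out / f"{doc.doc_id}.{name}.ann")


def read_corpus_dir(in_dir: str | Path,
                    source: str) -> tuple[list[Document], AnnotationSet]:
    """Read every ``<doc_id>.txt`` / ``<doc_id>.<source>.ann`` pair under
    ``in_dir``, in doc_id order."""
    in_dir = Path(in_dir)
    docs: list[Document] = []
    anns: list[Annotation] = []
    for txt in sorted(in_dir.glob("*.txt")):
        ann = in_dir / f"{txt.stem}.{source}.ann"
        if not ann.exists():
            raise FileNotFoundError(ann)
        doc, aset = read_standoff(ann, txt, source=source, doc_id=txt.stem)
        docs.append(doc)
        anns.extend(aset)
    return docs, AnnotationSet(source, anns)


# ---------------------------------------------------------------------------
# BIO tagging
# ---------------------------------------------------------------------------

def encode_bio(doc: Document, annotations: Iterable[Annotation],
               snap: bool = True) -> list[tuple[str, str]]:
    """Token-level IOB2 tags for one document's flat annotations.

    Tokens whose span intersects an annotation get ``B-<label>`` (first
    token) / ``I-<label>`` (subsequent); all others ``O``.  Annotations not
    token-aligned are snapped outward to token boundaries first (the
    guidelines forbid sub-tokenization); ``snap=False`` raises instead.
    Overlapping annotations are an error — flat tagging is only defined for
    non-nested sets.
    """
    anns = sorted(a for a in annotations if a.doc_id == doc.doc_id)
    for prev, cur in zip(anns, anns[1:]):
        if cur.overlaps(prev):
            raise ValueError(f"overlapping annotations: {prev} / {cur}")
    tokens = doc.tokens
    tags = ["O"] * len(tokens)
    for a in anns:
        covered = [i for i, (s, e) in enumerate(tokens)
                   if s < a.end and a.start < e]
        if not covered:
            continue
        if not snap:
            s0, e0 = tokens[covered[0]][0], tokens[covered[-1]][1]
            if (s0, e0) != (a.start, a.end):
                raise ValueError(f"annotation {a} is not token-aligned")
        if any(tags[i] != "O" for i in covered):
            raise ValueError(f"annotation {a} collides after snapping")
        tags[covered[0]] = f"B-{a.label}"
        for i in covered[1:]:
            tags[i] = f"I-{a.label}"
    return [(doc.text[s:e], tag) for (s, e), tag in zip(tokens, tags)]


def decode_bio(doc: Document, tags: Sequence[str],
               source: str = "system") -> AnnotationSet:
    """Recover character-span annotations from per-token IOB2 tags.

    An ``I-X`` following ``O`` or a different label is repaired to ``B-X``
    (ill-formed sequences are routine CRF output).  Unknown tag strings
    raise ``ValueError``.
    """
    tokens = doc.tokens
    if len(tags) != len(tokens):
        raise ValueError(
            f"{len(tags)} tags for {len(tokens)} tokens in {doc.doc_id!r}"
        )
    anns: list[Annotation] = []
    cur_label: str | None = None
    cur_start = cur_end = 0
    for (s, e), tag in zip(tokens, tags):
        if tag == "O":
            label = None
        elif tag[:2] in ("B-", "I-") and len(tag) > 2:
            label = tag[2:]
        else:
            raise ValueError(f"unknown BIO tag {tag!r}")
        begin = tag.startswith("B-") or (label is not None and label != cur_label)
        if cur_label is not None and (label is None or begin):
            anns.append(Annotation(doc.doc_id, cur_start, cur_end,
                                   cur_label, source))
            cur_label = None
        if label is not None and (begin or cur_label is None):
            cur_label, cur_start, cur_end = label, s, e
        elif label is not None:
            cur_end = e
    if cur_label is not None:
        anns.append(Annotation(doc.doc_id, cur_start, cur_end, cur_label, source))
    return AnnotationSet(source, anns)


# ---------------------------------------------------------------------------
# CoNLL two-column interchange
# ---------------------------------------------------------------------------

def write_conll(path: str | Path,
                tagged_docs: Mapping[str, Sequence[tuple[str, str]]]) -> None:
    """One ``token<TAB>tag`` line per token, blank line between documents,
    a ``# doc_id = <id>`` comment opening each document block."""
    lines: list[str] = []
    for doc_id in sorted(tagged_docs):
        lines.append(f"# doc_id = {doc_id}")
        for token, tag in tagged_docs[doc_id]:
            lines.append(f"{token}\t{tag}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


def read_conll(path: str | Path) -> dict[str, list[tuple[str, str]]]:
    out: dict[str, list[tuple[str, str]]] = {}
    cur: list[tuple[str, str]] | None = None
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.startswith("# doc_id = "):
            cur = out.setdefault(line[len("# doc_id = "):], [])
        elif not line.strip():
            cur = None
        else:
            token, _, tag = line.partition("\t")
            if cur is None:
                cur = out.setdefault(f"doc{len(out)}", [])
            cur.append((token, tag))
    return out
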