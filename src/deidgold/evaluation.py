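"""Span-match evaluation: exact and partial matching, Annotated /
Retrieved / Relevant bookkeeping, precision/recall/F, and the
false-positive audit.

Two matching modes, following the usual de-identification conventions:

* **exact** — a prediction is correct iff a gold annotation has the same
  token-aligned span and the same label;
* **partial** — a prediction is correct iff it overlaps a same-label gold
  annotation on the character level (minimum overlap fraction
  configurable; default: any overlap).

Matching is one-to-one: each gold annotation credits at most one
prediction and vice versa.  Candidates are matched greedily left-to-right,
each prediction taking the earliest-ending unmatched same-label gold it
overlaps; for non-overlapping interval sets this greedy choice attains the
maximum matching, so ``relevant`` is symmetric in the two arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence


import pandas as pd

from .corpus_model import Annotation, AnnotationSet, Document

__all__ = [
    "ClassCounts",
    "MatchCounts",
    "PRF",
    "EvalReport",
    "match_pairs",
    "count_matches",
    "compute_prf",
    "per_class_report",
    "fp_audit",
]


@dataclass(frozen=True)
class ClassCounts:
    """Annotated (gold), retrieved (system) and relevant (correctly
    retrieved) counts for one class or pooled over all classes."""

    annotated: int = 0
    retrieved: int = 0
    relevant: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.relevant <= min(self.annotated, self.retrieved)):
            raise ValueError(
                f"relevant={self.relevant} exceeds min(annotated="
                f"{self.annotated}, retrieved={self.retrieved})"
            )

    def __add__(self, other: "ClassCounts") -> "ClassCounts":
        return ClassCounts(
            self.annotated + other.annotated,
            self.retrieved + other.retrieved,
            self.relevant + other.relevant,
        )


@dataclass
class MatchCounts:
    """Per-class counts for one matching mode, plus the pooled total."""

    mode: str
    per_class: dict[str, ClassCounts] = field(default_factory=dict)

    @property
    def overall(self) -> ClassCounts:
        total = ClassCounts()
        for c in self.per_class.values():
            total = total + c
        return total


@dataclass(frozen=True)
class PRF:
    precision: float
    recall: float
    f_score: float
    precision_defined: bool = True
    recall_defined: bool = True


def compute_prf(counts: ClassCounts) -> PRF:
    """P = relevant/retrieved, R = relevant/annotated, F = 2PR/(P+R).

    A zero denominator makes the statistic undefined; it is reported as 0.0
    with the corresponding ``*_defined`` flag cleared.
    """
    p_def = counts.retrieved > 0
    r_def = counts.annotated > 0
    p = counts.relevant / counts.retrieved if p_def else 0.0
    r = counts.relevant / counts.annotated if r_def else 0.0
    f = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return PRF(p, r, f, p_def, r_def)


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def _aligned_span(ann: Annotation,
                  doc: Document | None) -> tuple[int, int]:
    """Token-aligned character span (snapped outward); raw span if no
    document is available for token boundaries."""
    if doc is None:
        return (ann.start, ann.end)
    s, e = ann.start, ann.end
    for ts, te in doc.tokens:
        if ts < ann.end and ann.start < te:
            s = min(s, ts)
            e = max(e, te)
    return (s, e)


def _overlap_ok(g: Annotation, p: Annotation, min_overlap: float) -> bool:
    ov = min(g.end, p.end) - max(g.start, p.start)
    if ov <= 0:
        return False
    if min_overlap <= 0:
        return True
    shorter = min(g.end - g.start, p.end - p.start)
    return ov >= min_overlap * shorter


def match_pairs(gold: AnnotationSet | Sequence[Annotation],
                pred: AnnotationSet | Sequence[Annotation],
                mode: str,
                docs: Mapping[str, Document] | None = None,
                min_overlap: float = 0.0) -> list[tuple[Annotation, Annotation]]:
    """One-to-one (gold, prediction) matches under ``mode``.

    Matching is independent per (document, label) group.  Deterministic:
    predictions are visited in span order and take the earliest-ending
    unmatched gold candidate.
    """
    if mode not in ("exact", "partial"):
        raise ValueError(f"unknown mode {mode!r}")
    by_key_gold: dict[tuple[str, str], list[Annotation]] = {}
    for a in gold:
        by_key_gold.setdefault((a.doc_id, a.label), []).append(a)
    pairs: list[tuple[Annotation, Annotation]] = []
    by_key_pred: dict[tuple[str, str], list[Annotation]] = {}
    for a in pred:
        by_key_pred.setdefault((a.doc_id, a.label), []).append(a)
    for key, preds in sorted(by_key_pred.items()):
        golds = sorted(by_key_gold.get(key, []))
        if not golds:
            continue
        doc = docs.get(key[0]) if docs else None
        if mode == "exact":
            gold_by_span = {_aligned_span(g, doc): g for g in golds}
            taken: set[tuple[int, int]] = set()
            for p in sorted(preds):
                span = _aligned_span(p, doc)
                if span in gold_by_span and span not in taken:
                    taken.add(span)
                    pairs.append((gold_by_span[span], p))
        else:
            unmatched = list(golds)  # sorted by (start, end)
            for p in sorted(preds):
                for i, g in enumerate(unmatched):
                    if _overlap_ok(g, p, min_overlap):
                        pairs.append((g, p))
                        del unmatched[i]
                        break
    return pairs


def count_matches(gold: AnnotationSet, pred: AnnotationSet, mode: str,
                  docs: Mapping[str, Document] | Sequence[Document] | None = None,
                  min_overlap: float = 0.0) -> MatchCounts:
    """Annotated/Retrieved/Relevant per class under one matching mode.

    Both sets must be internally non-overlapping (enforced by
    :class:`AnnotationSet`).  ``docs`` supplies token boundaries for the
    token-level exact mode; without it exact falls back to raw character
    spans.
    """
    doc_map = _as_doc_map(docs)
    counts: dict[str, ClassCounts] = {}
    ann_by_label: dict[str, int] = {}
    ret_by_label: dict[str, int] = {}
    for a in gold:
        ann_by_label[a.label] = ann_by_label.get(a.label, 0) + 1
    for a in pred:
        ret_by_label[a.label] = ret_by_label.get(a.label, 0) + 1
    rel_by_label: dict[str, int] = {}
    for g, _ in match_pairs(gold, pred, mode, doc_map, min_overlap):
        rel_by_label[g.label] = rel_by_label.get(g.label, 0) + 1
    for label in sorted(set(ann_by_label) | set(ret_by_label)):
        counts[label] = ClassCounts(
            annotated=ann_by_label.get(label, 0),
            retrieved=ret_by_label.get(label, 0),
            relevant=rel_by_label.get(label, 0),
        )
    return MatchCounts(mode=mode, per_class=counts)


def _as_doc_map(docs) -> dict[str, Document] | None:
    if docs is None:
        return None
    if isinstance(docs, Mapping):
        return dict(docs)
    return {d.doc_id: d for d in docs}


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Exact- and partial-mode counts with per-class, micro (pooled) and
    macro (unweighted class mean) precision/recall/F."""

    exact: MatchCounts
    partial: MatchCounts

    def to_frame(self) -> pd.DataFrame:
        """One row per class plus ``__micro__`` and ``__macro__`` rows;
        columns mirror the Annotated/Retrieved/Relevant layout for both
        matching modes."""
        labels = sorted(set(self.exact.per_class) | set(self.partial.per_class))
        rows = []
        for label in labels:
            rows.append(self._row(label,
                                  self.exact.per_class.get(label, ClassCounts()),
                                  self.partial.per_class.get(label, ClassCounts())))
        rows.append(self._row("__micro__", self.exact.overall,
                              self.partial.overall))
        macro = {"class": "__macro__"}
        if labels:
            for mode in ("exact", "partial"):
                mc = self.exact if mode == "exact" else self.partial
                prfs = [compute_prf(mc.per_class.get(l, ClassCounts()))
                        for l in labels]
                macro[f"{mode}_precision"] = sum(x.precision for x in prfs) / len(prfs)
                macro[f"{mode}_recall"] = sum(x.recall for x in prfs) / len(prfs)
                macro[f"{mode}_f"] = sum(x.f_score for x in prfs) / len(prfs)
        rows.append(macro)
        return pd.DataFrame(rows).set_index("class")

    @staticmethod
    def _row(name: str, ex: ClassCounts, pa: ClassCounts) -> dict:
        row = {"class": name,
               "annotated": ex.annotated,
               "retrieved": ex.retrieved,
               "relevant_exact": ex.relevant,
               "relevant_partial": pa.relevant}
        for mode, c in (("exact", ex), ("partial", pa)):
            prf = compute_prf(c)
            row[f"{mode}_precision"] = prf.precision
            row[f"{mode}_recall"] = prf.recall
            row[f"{mode}_f"] = prf.f_score
        return row

    def micro(self, mode: str) -> PRF:
        mc = self.exact if mode == "exact" else self.partial
        return compute_prf(mc.overall)


def per_class_report(gold: AnnotationSet, pred: AnnotationSet,
                     docs=None, min_overlap: float = 0.0) -> EvalReport:
    """Evaluate ``pred`` against ``gold`` in both matching modes."""
    return EvalReport(
        exact=count_matches(gold, pred, "exact", docs, min_overlap),
        partial=count_matches(gold, pred, "partial", docs, min_overlap),
    )


def fp_audit(gold: AnnotationSet, pred: AnnotationSet,
             docs: Mapping[str, Document] | Sequence[Document],
             context: int = 40) -> list[dict]:
    """Every prediction unmatched in exact mode, with surrounding text for
    human re-adjudication.

    System-found spans the annotators missed show up here; auditing them is
    how genuinely missed PHI is recovered.  Length always equals
    retrieved − relevant(exact).  Deterministic (doc_id, start) order.
    """
    doc_map = _as_doc_map(docs)
    matched = {id(p) for _, p in match_pairs(gold, pred, "exact", doc_map)}
    rows = []
    for p in sorted(pred):
        if id(p) in matched:
            continue
        doc = doc_map[p.doc_id]
        lo = max(0, p.start - context)
        hi = min(len(doc.text), p.end + context)
        rows.append({
            "doc_id": p.doc_id,
            "start": p.start,
            "end": p.end,
            "label": p.label,
            "surface": doc.text[p.start:p.end],
            "context": doc.text[lo:hi],
        })
    return rows
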