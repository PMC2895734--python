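"""Refined annotation guidelines as an executable, ordered rule engine —
the machinery behind the manual consensus gold standard.

Each rule is a declarative transformation over one document's annotations.
The shipped default rule set realizes the refined guidelines:

1. ``no_subtoken`` — spans are snapped outward to whole tokens (an
   instance must never be sub-tokenized: a span on ``34`` inside
   ``34-årig`` covers the whole word).
2. ``location_merge`` — ``Street_Address``, ``Town``, ``Municipality``,
   ``Country`` and ``Organization`` collapse into ``Location``.
3. ``largest_span`` — adjacent same-label ``Location`` /
   ``Health_Care_Unit`` annotations separated only by punctuation or
   whitespace merge into one maximal span (a full address is one
   instance).
4. ``date_no_weekday`` — dates never include weekdays: leading/trailing
   weekday tokens are stripped from ``Date_Part`` / ``Full_Date`` spans;
   a span that was only a weekday is deleted.  The ``Date_Part`` /
   ``Full_Date`` division itself is kept.
5. ``unit_specificity`` — a ``Health_Care_Unit`` is kept only if it
   denotes a specific unit; a bare generic term (``Geriatriken``) is
   deleted.  What counts as generic is a configurable lexicon.
6. ``delete_classes`` — ``Relation`` and ``Ethnicity`` are dropped
   entirely (judged not to identify patients).

Boundary fixes run before label logic and deletions run last, so the
change log tells the complete story.  Every deletion, relabeling, boundary
move and merge is logged; ``len(output) == len(input) - deletions`` (where
an absorbed merge member counts as a deletion) holds by construction, and
applying the rules twice is a no-op.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import yaml

from .corpus_model import (
    Annotation,
    AnnotationSet,
    Document,
    snap_to_tokens,
)

__all__ = [
    "ChangeRecord",
    "GuidelineRule",
    "GuidelineRuleSet",
    "default_ruleset",
    "apply_guidelines",
    "load_ruleset",
    "save_ruleset",
]

_PUNCT = set(string.punctuation) | {"…", "–", "—"}

LOCATION_MERGE = {
    "Street_Address": "Location",
    "Town": "Location",
    "Municipality": "Location",
    "Country": "Location",
    "Organization": "Location",
}

DELETED_CLASSES = ("Relation", "Ethnicity")


@dataclass(frozen=True)
class ChangeRecord:
    rule: str
    action: str  # delete | relabel | move | merge
    doc_id: str
    before: tuple[int, int]
    after: tuple[int, int] | None
    label_before: str
    label_after: str | None


def _load_lexicon(name: str) -> frozenset[str]:
    data = resources.files("deidgold.data.lexicons").joinpath(f"{name}.txt")
    return frozenset(
        line.strip().lower()
        for line in data.read_text(encoding="utf-8").splitlines()
        if line.strip()
    )


@dataclass
class GuidelineRule:
    """One named transformation over a document's annotation list."""

    name: str
    apply: Callable[[list[Annotation], Document, "GuidelineRuleSet",
                     list[ChangeRecord]], list[Annotation]]
    params: dict = field(default_factory=dict)


@dataclass
class GuidelineRuleSet:
    """Ordered rules plus the lexicons they consult."""

    rules: list[GuidelineRule]
    weekdays: frozenset[str] = field(default_factory=lambda: _load_lexicon("weekdays"))
    generic_units: frozenset[str] = field(
        default_factory=lambda: _load_lexicon("generic_units"))

    def __post_init__(self) -> None:
        names = [r.name for r in self.rules]
        if len(names) != len(set(names)):
            raise ValueError("rule names must be unique")


# ---------------------------------------------------------------------------
# Individual rules (each independently usable)
# ---------------------------------------------------------------------------

def rule_no_subtoken(anns, doc, rset, log):
    out = []
    for a in anns:
        snapped = snap_to_tokens(a, doc)
        if snapped.span != a.span:
            log.append(ChangeRecord("no_subtoken", "move", a.doc_id,
                                    a.span, snapped.span, a.label, a.label))
        out.append(snapped)
    return out


def rule_location_merge(anns, doc, rset, log):
    out = []
    for a in anns:
        target = LOCATION_MERGE.get(a.label)
        if target is None:
            out.append(a)
        else:
            log.append(ChangeRecord("location_merge", "relabel", a.doc_id,
                                    a.span, a.span, a.label, target))
            out.append(Annotation(a.doc_id, a.start, a.end, target, a.source))
    return out


def _gap_is_joinable(text: str) -> bool:
    return all(ch.isspace() or ch in _PUNCT for ch in text)


def rule_largest_span(anns, doc, rset, log,
                      labels=("Location", "Health_Care_Unit")):
    """Merge runs of adjacent same-label annotations whose gaps are only
    whitespace/punctuation into a single maximal-span annotation."""
    out = []
    anns = sorted(anns)
    i = 0
    while i < len(anns):
        a = anns[i]
        if a.label not in labels:
            out.append(a)
            i += 1
            continue
        j = i
        end = a.end
        while (j + 1 < len(anns)
               and anns[j + 1].label == a.label
               and _gap_is_joinable(doc.text[end:anns[j + 1].start])):
            j += 1
            end = max(end, anns[j].end)
        if j > i:
            merged = Annotation(a.doc_id, a.start, end, a.label, a.source)
            for absorbed in anns[i + 1:j + 1]:
                log.append(ChangeRecord("largest_span", "merge", a.doc_id,
                                        absorbed.span, merged.span,
                                        absorbed.label, merged.label))
            log.append(ChangeRecord("largest_span", "move", a.doc_id,
                                    a.span, merged.span, a.label, a.label))
            out.append(merged)
        else:
            out.append(a)
        i = j + 1
    return out


def rule_date_no_weekday(anns, doc, rset, log):
    out = []
    for a in anns:
        if a.label not in ("Date_Part", "Full_Date"):
            out.append(a)
            continue
        covered = [(s, e) for s, e in doc.tokens if s < a.end and a.start < e]
        while covered and doc.text[covered[0][0]:covered[0][1]].lower() in rset.weekdays:
            covered.pop(0)
        while covered and doc.text[covered[-1][0]:covered[-1][1]].lower() in rset.weekdays:
            covered.pop()
        if not covered:
            log.append(ChangeRecord("date_no_weekday", "delete", a.doc_id,
                                    a.span, None, a.label, None))
            continue
        new_span = (covered[0][0], covered[-1][1])
        if new_span != a.span:
            log.append(ChangeRecord("date_no_weekday", "move", a.doc_id,
                                    a.span, new_span, a.label, a.label))
            a = Annotation(a.doc_id, new_span[0], new_span[1],
                           a.label, a.source)
        out.append(a)
    return out


def _normalize_surface(text: str) -> str:
    return "".join(ch for ch in text if ch not in _PUNCT).strip().lower()


def rule_unit_specificity(anns, doc, rset, log):
    """Delete a Health_Care_Unit whose surface is a bare generic term
    (every word generic); anything naming a specific unit survives."""
    out = []
    for a in anns:
        if a.label != "Health_Care_Unit":
            out.append(a)
            continue
        words = _normalize_surface(doc.text[a.start:a.end]).split()
        generic = bool(words) and all(w in rset.generic_units for w in words)
        if generic:
            log.append(ChangeRecord("unit_specificity", "delete", a.doc_id,
                                    a.span, None, a.label, None))
        else:
            out.append(a)
    return out


def rule_delete_classes(anns, doc, rset, log, classes=DELETED_CLASSES):
    out = []
    for a in anns:
        if a.label in classes:
            log.append(ChangeRecord("delete_classes", "delete", a.doc_id,
                                    a.span, None, a.label, None))
        else:
            out.append(a)
    return out


_RULE_REGISTRY: dict[str, Callable] = {
    "no_subtoken": rule_no_subtoken,
    "location_merge": rule_location_merge,
    "largest_span": rule_largest_span,
    "date_no_weekday": rule_date_no_weekday,
    "unit_specificity": rule_unit_specificity,
    "delete_classes": rule_delete_classes,
}

_DEFAULT_ORDER = ("no_subtoken", "location_merge", "date_no_weekday",
                  "largest_span", "unit_specificity", "delete_classes")


def default_ruleset() -> GuidelineRuleSet:
    """The refined-guideline rules in their canonical order."""
    return GuidelineRuleSet(
        rules=[GuidelineRule(n, _RULE_REGISTRY[n]) for n in _DEFAULT_ORDER]
    )


def _dedupe_resolve(anns: list[Annotation],
                    log: list[ChangeRecord]) -> list[Annotation]:
    """After boundary moves/merges, identical or overlapping survivors are
    collapsed (keep the longest, then leftmost); collapses are logged."""
    anns = sorted(anns,
                  key=lambda a: (a.start, -(a.end - a.start), a.end, a.label))
    out: list[Annotation] = []
    for a in anns:
        prev = out[-1] if out else None
        if prev is not None and a.start < prev.end:  # covers duplicates too
            log.append(ChangeRecord("resolve_overlap", "merge", a.doc_id,
                                    a.span, prev.span, a.label, prev.label))
            continue
        out.append(a)
    return out


def apply_guidelines(aset: AnnotationSet,
                     docs: Mapping[str, Document] | Sequence[Document],
                     ruleset: GuidelineRuleSet | None = None,
                     source: str = "consensus_manual",
                     ) -> tuple[AnnotationSet, list[ChangeRecord]]:
    """Run the ordered rules over every document's annotations.

    Returns the transformed (non-overlapping) set and the complete change
    log.  Count bookkeeping: ``len(output) == len(input) - #deletions``
    where merges log one deletion-equivalent per absorbed annotation.
    Applying the same rules to the output changes nothing.
    """
    ruleset = ruleset or default_ruleset()
    for rule in ruleset.rules:
        if rule.name not in _RULE_REGISTRY and rule.apply is None:
            raise ValueError(f"unknown rule {rule.name!r}")
    doc_map = docs if isinstance(docs, Mapping) else {d.doc_id: d for d in docs}
    log: list[ChangeRecord] = []
    out: list[Annotation] = []
    for doc_id in sorted({a.doc_id for a in aset}):
        doc = doc_map[doc_id]
        anns = sorted(aset.for_doc(doc_id))
        for rule in ruleset.rules:
            anns = rule.apply(anns, doc, ruleset, log)
        anns = _dedupe_resolve(anns, log)
        out.extend(anns)
    result = AnnotationSet(source, out)
    return result, log


def deletions(log: Iterable[ChangeRecord]) -> int:
    """Count of log entries that remove an annotation from the set
    (explicit deletions plus absorbed merge members)."""
    return sum(1 for r in log if r.action in ("delete", "merge"))


def change_log_frame(log: Sequence[ChangeRecord]):
    import pandas as pd

    return pd.DataFrame([r.__dict__ for r in log])


# ---------------------------------------------------------------------------
# Declarative config round-trip
# ---------------------------------------------------------------------------

def save_ruleset(ruleset: GuidelineRuleSet, path: str | Path) -> None:
    payload = {
        "rules": [{"name": r.name, **({"params": r.params} if r.params else {})}
                  for r in ruleset.rules],
        "weekdays": sorted(ruleset.weekdays),
        "generic_units": sorted(ruleset.generic_units),
    }
    Path(path).write_text(yaml.safe_dump(payload, allow_unicode=True),
                          encoding="utf-8")


def load_ruleset(path: str | Path) -> GuidelineRuleSet:
    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    rules = []
    for entry in payload["rules"]:
        name = entry["name"]
        if name not in _RULE_REGISTRY:
            raise ValueError(f"unknown rule {name!r}; "
                             f"known: {sorted(_RULE_REGISTRY)}")
        rules.append(GuidelineRule(name, _RULE_REGISTRY[name],
                                   entry.get("params", {})))
    return GuidelineRuleSet(
        rules=rules,
        weekdays=frozenset(w.lower() for w in payload.get("weekdays", [])),
        generic_units=frozenset(
            g.lower() for g in payload.get("generic_units", [])),
    )
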