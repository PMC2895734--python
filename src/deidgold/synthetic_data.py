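"""Synthetic clinical-style corpus generator with gold PHI annotations,
plus a stochastic model of imperfect human annotators.

The generator stands in for a confidential record corpus: it assembles
short pseudo-Swedish clinical sentences from a filler vocabulary and
inserts PHI surface forms (names, care units, dates, phone numbers, ages,
addresses…) at recorded character offsets, so the gold annotations are
exact by construction.  All entries in the shipped lexicons are fictional.

Design points that downstream stages rely on:

* the class-frequency skew is heavy-tailed with ``Health_Care_Unit`` the
  strictly most frequent class, as in real record audits;
* generic-unit distractors (``Geriatriken`` …) are inserted *without*
  gold annotation, so the guideline filter has something to catch;
* a weekday word sometimes precedes a date insertion, outside the gold
  span, exercising the weekday-stripping guideline;
* everything is driven by explicit integer seeds — identical
  configuration means byte-identical output.

:class:`AnnotatorErrorModel` perturbs the gold set into one annotator's
set: each gold span is dropped with ``miss_rate``, survivors are
relabeled through a confusion row and boundary-jittered by one token with
``boundary_jitter``, and spurious spans (never overlapping gold) are added
at ``spurious_rate`` per document.  Tuning miss/jitter/confusion moves the
pairwise agreement; asymmetric miss rates reproduce large per-annotator
total differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .corpus_model import (
    Annotation,
    AnnotationSet,
    AnnotationStudy,
    Document,
)

__all__ = [
    "SynthConfig",
    "AnnotatorErrorModel",
    "default_lexicons",
    "DEFAULT_CLASS_FREQUENCIES",
    "default_error_models",
    "generate_gold_corpus",
    "simulate_annotator",
    "build_annotation_study",
]


def _lexicon(name: str) -> tuple[str, ...]:
    data = resources.files("deidgold.data.lexicons").joinpath(f"{name}.txt")
    return tuple(
        line.strip() for line in data.read_text(encoding="utf-8").splitlines()
        if line.strip()
    )


def default_lexicons() -> dict[str, tuple[str, ...]]:
    """Surface-form lexicons per PHI class (all fictional)."""
    first = _lexicon("first_names")
    last = _lexicon("last_names")
    return {
        "First_Name": first,
        "Clinician_First_Name": first,
        "Patient_First_Name": first,
        "Relative_First_Name": first,
        "Last_Name": last,
        "Clinician_Last_Name": last,
        "Patient_Last_Name": last,
        "Relative_Last_Name": last,
        "Town": _lexicon("towns"),
        "Street_Address": _lexicon("streets"),
        "Municipality": _lexicon("municipalities"),
        "Country": _lexicon("countries"),
        "Organization": _lexicon("organizations"),
        "Health_Care_Unit": _lexicon("health_care_units"),
        "Relation": _lexicon("relations"),
        "Ethnicity": _lexicon("ethnicities"),
    }


#: Relative gold class weights.  Health_Care_Unit is strictly the largest,
#: names and dates follow, identifiers are rare — the skew typical of
#: free-text clinical notes.
DEFAULT_CLASS_FREQUENCIES: dict[str, float] = {
    "Health_Care_Unit": 0.26,
    "Full_Date": 0.08,
    "Date_Part": 0.08,
    "First_Name": 0.07,
    "Last_Name": 0.07,
    "Clinician_First_Name": 0.04,
    "Clinician_Last_Name": 0.04,
    "Town": 0.05,
    "Age": 0.05,
    "Phone_Number": 0.05,
    "Street_Address": 0.03,
    "Relation": 0.03,
    "Patient_First_Name": 0.02,
    "Patient_Last_Name": 0.02,
    "Organization": 0.02,
    "Relative_First_Name": 0.01,
    "Relative_Last_Name": 0.01,
    "Age_Over_89": 0.01,
    "Municipality": 0.01,
    "Country": 0.01,
    "Ethnicity": 0.01,
    "Social_Security_Number": 0.01,
    "E-mail_Address": 0.01,
}


@dataclass(frozen=True)
class SynthConfig:
    """Corpus generation parameters.

    ``phi_per_token`` is the expected number of PHI insertions per filler
    token (~1 instance per 13 tokens by default, a density at which every
    major class gets enough instances to learn from at desk scale).
    """

    n_documents: int = 100
    tokens_per_doc: int = 200
    class_frequencies: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FREQUENCIES))
    lexicons: Mapping[str, tuple[str, ...]] = field(
        default_factory=default_lexicons)
    phi_per_token: float = 0.075
    distractor_rate: float = 1.0   # generic-unit words per doc, unannotated
    weekday_rate: float = 0.3      # P(weekday word precedes a date insertion)
    seed: int = 0

    def __post_init__(self) -> None:
        freqs = dict(self.class_frequencies)
        if not freqs or any(w < 0 for w in freqs.values()) \
                or not any(w > 0 for w in freqs.values()):
            raise ValueError("class_frequencies must contain a positive weight")
        lex = dict(self.lexicons)
        for label, w in freqs.items():
            if w > 0 and not (label in _PATTERN_CLASSES or lex.get(label)):
                raise ValueError(f"no lexicon for positive-weight label {label!r}")
        object.__setattr__(self, "class_frequencies", freqs)
        object.__setattr__(self, "lexicons", lex)


@dataclass(frozen=True)
class AnnotatorErrorModel:
    """Stochastic annotator behaviour relative to the gold standard."""

    miss_rate: float = 0.0
    boundary_jitter: float = 0.0
    confusion: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    spurious_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.miss_rate, self.boundary_jitter):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.spurious_rate < 0:
            raise ValueError("spurious_rate must be non-negative")
        conf = {k: dict(v) for k, v in dict(self.confusion).items()}
        for label, row in conf.items():
            total = sum(row.values())
            if abs(total - 1.0) > 1e-9 or any(p < 0 for p in row.values()):
                raise ValueError(f"confusion row for {label!r} must be a "
                                 f"distribution (sums to {total})")
        object.__setattr__(self, "confusion", conf)


def diagonal_confusion(labels: Sequence[str], diag: float,
                       confusable: Mapping[str, Sequence[str]] | None = None,
                       ) -> dict[str, dict[str, float]]:
    """Confusion rows keeping a label with probability ``diag`` and
    spreading the rest over its confusable alternatives (or all other
    labels when none are given)."""
    rows: dict[str, dict[str, float]] = {}
    labels = sorted(labels)
    for lab in labels:
        alts = list((confusable or {}).get(lab, [])) or [l for l in labels
                                                         if l != lab]
        row = {lab: diag}
        for a in alts:
            row[a] = row.get(a, 0.0) + (1.0 - diag) / len(alts)
        rows[lab] = row
    return rows


#: Alternatives annotators actually mix up: refinement siblings/parents and
#: the location/care-unit ambiguity.
CONFUSABLE: dict[str, tuple[str, ...]] = {
    "First_Name": ("Clinician_First_Name", "Patient_First_Name"),
    "Clinician_First_Name": ("First_Name",),
    "Patient_First_Name": ("First_Name",),
    "Relative_First_Name": ("First_Name",),
    "Last_Name": ("Clinician_Last_Name", "Patient_Last_Name"),
    "Clinician_Last_Name": ("Last_Name",),
    "Patient_Last_Name": ("Last_Name",),
    "Relative_Last_Name": ("Last_Name",),
    "Town": ("Health_Care_Unit", "Municipality"),
    "Municipality": ("Town",),
    "Health_Care_Unit": ("Town", "Organization"),
    "Organization": ("Health_Care_Unit",),
    "Full_Date": ("Date_Part",),
    "Date_Part": ("Full_Date",),
    "Age": ("Age_Over_89",),
    "Age_Over_89": ("Age",),
}


def default_error_models(seed: int = 0) -> list[AnnotatorErrorModel]:
    """Three annotators with asymmetric miss rates (their totals differ
    visibly), moderate boundary jitter and label confusion — calibrated so
    the mean pairwise exact-match agreement lands in the mid-0.6 band."""
    labels = sorted(DEFAULT_CLASS_FREQUENCIES)
    conf = diagonal_confusion(labels, diag=0.95, confusable=CONFUSABLE)
    return [
        AnnotatorErrorModel(miss_rate=0.08, boundary_jitter=0.08,
                            confusion=conf, spurious_rate=0.15,
                            seed=seed * 3 + 1),
        AnnotatorErrorModel(miss_rate=0.15, boundary_jitter=0.08,
                            confusion=conf, spurious_rate=0.15,
                            seed=seed * 3 + 2),
        AnnotatorErrorModel(miss_rate=0.25, boundary_jitter=0.08,
                            confusion=conf, spurious_rate=0.15,
                            seed=seed * 3 + 3),
    ]


# ---------------------------------------------------------------------------
# Gold corpus generation
# ---------------------------------------------------------------------------

_PATTERN_CLASSES = frozenset({
    "Phone_Number", "Full_Date", "Date_Part", "Age", "Age_Over_89",
    "Social_Security_Number", "E-mail_Address",
})

_MONTHS = ("januari", "februari", "mars", "april", "maj", "juni", "juli",
           "augusti", "september", "oktober", "november", "december")


def _pattern_surface(label: str, rng: np.random.Generator,
                     lexicons: Mapping[str, tuple[str, ...]]) -> str:
    ri = rng.integers
    if label == "Phone_Number":
        if ri(2):
            return f"08-{ri(100, 1000)} {ri(100, 1000)} {ri(10, 100)}"
        return f"07{ri(10)}-{ri(100, 1000)} {ri(10, 100)} {ri(10, 100)}"
    if label == "Full_Date":
        y, m, d = ri(1998, 2010), ri(1, 13), ri(1, 29)
        if ri(2):
            return f"{y}-{m:02d}-{d:02d}"
        return f"{d}/{m} {y}"
    if label == "Date_Part":
        m, d = ri(1, 13), ri(1, 29)
        if ri(2):
            return f"{d}/{m}"
        return f"{d} {_MONTHS[m - 1]}"
    if label == "Age":
        age = ri(18, 90)
        return f"{age}-årig" if ri(2) else f"{age} år"
    if label == "Age_Over_89":
        age = ri(90, 104)
        return f"{age}-årig" if ri(2) else f"{age} år"
    if label == "Social_Security_Number":
        return f"19{ri(20, 90)}{ri(1, 13):02d}{ri(1, 29):02d}-{ri(1000, 10000)}"
    if label == "E-mail_Address":
        first = rng.choice(lexicons.get("First_Name", ("anna",)))
        last = rng.choice(lexicons.get("Last_Name", ("svensson",)))
        host = rng.choice(["exemplet.se", "vardpost.se", "klinikmail.se"])
        return f"{_ascii(first.lower())}.{_ascii(last.lower())}@{host}"
    raise ValueError(label)


def _ascii(s: str) -> str:
    return (s.replace("å", "a").replace("ä", "a").replace("ö", "o")
            .replace("é", "e"))


def _surface_for(label: str, rng: np.random.Generator,
                 cfg: SynthConfig) -> str:
    if label in _PATTERN_CLASSES:
        return _pattern_surface(label, rng, cfg.lexicons)
    forms = cfg.lexicons[label]
    return str(forms[rng.integers(len(forms))])


def generate_gold_corpus(cfg: SynthConfig,
                         ) -> tuple[list[Document], AnnotationSet]:
    """Assemble the corpus and its exact gold annotations.

    Documents are sequences of short sentences; PHI surfaces are inserted
    between filler tokens and their character offsets recorded as gold.
    Every gold annotation's text slice equals the inserted surface form.
    """
    rng = np.random.default_rng(cfg.seed)
    labels = sorted(l for l, w in cfg.class_frequencies.items() if w > 0)
    weights = np.array([cfg.class_frequencies[l] for l in labels], float)
    weights = weights / weights.sum()
    filler = _lexicon("filler")
    weekdays = _lexicon("weekdays")
    generic_units = _lexicon("generic_units")

    docs: list[Document] = []
    gold: list[Annotation] = []
    width = len(str(max(cfg.n_documents - 1, 1)))
    for d in range(cfg.n_documents):
        doc_id = f"doc{d:0{width}d}"
        parts: list[str] = []   # pieces joined by single spaces
        spans: list[tuple[int, int, str]] = []
        pos = 0                 # running char offset
        n_tokens = 0
        distractors_left = rng.poisson(cfg.distractor_rate)
        while n_tokens < cfg.tokens_per_doc:
            sent_len = int(rng.integers(5, 10))
            for _ in range(sent_len):
                if rng.random() < cfg.phi_per_token:
                    label = labels[rng.choice(len(labels), p=weights)]
                    surface = _surface_for(label, rng, cfg)
                    if (label in ("Date_Part", "Full_Date")
                            and rng.random() < cfg.weekday_rate):
                        wd = str(weekdays[rng.integers(len(weekdays))])
                        parts.append(wd)
                        pos += len(wd) + 1
                        n_tokens += 1
                    parts.append(surface)
                    spans.append((pos, pos + len(surface), label))
                    pos += len(surface) + 1
                    n_tokens += len(surface.split())
                elif distractors_left > 0 and rng.random() < 0.05:
                    word = str(generic_units[rng.integers(len(generic_units))])
                    parts.append(word)
                    pos += len(word) + 1
                    n_tokens += 1
                    distractors_left -= 1
                else:
                    word = str(filler[rng.integers(len(filler))])
                    parts.append(word)
                    pos += len(word) + 1
                    n_tokens += 1
            parts.append(".")
            pos += 2
            n_tokens += 1
        text = " ".join(parts)
        doc = Document(doc_id, text)
        for start, end, label in spans:
            gold.append(Annotation(doc_id, start, end, label, "gold"))
        docs.append(doc)
    return docs, AnnotationSet("gold", gold)


# ---------------------------------------------------------------------------
# Annotator simulation
# ---------------------------------------------------------------------------

def simulate_annotator(gold: AnnotationSet, model: AnnotatorErrorModel,
                       source_id: str,
                       docs: Mapping[str, Document] | Sequence[Document],
                       ) -> AnnotationSet:
    """One imperfect annotator's set derived from the gold standard.

    Order of perturbations per gold annotation: miss, then relabel through
    the confusion row, then one-token boundary jitter.  Spurious
    annotations land on token spans that touch neither gold nor each
    other.  Deterministic given the model's seed.
    """
    rng = np.random.default_rng(model.seed)
    doc_map = docs if isinstance(docs, Mapping) else {d.doc_id: d for d in docs}
    out: list[Annotation] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for a in gold:
        occupied.setdefault(a.doc_id, []).append((a.start, a.end))
    kept_by_doc: dict[str, list[Annotation]] = {}
    claimed: dict[str, list[tuple[int, int]]] = {}
    for a in gold:
        if rng.random() < model.miss_rate:
            continue
        label = a.label
        row = model.confusion.get(label)
        if row:
            cands = sorted(row)
            probs = np.array([row[c] for c in cands])
            label = cands[rng.choice(len(cands), p=probs / probs.sum())]
        ann = Annotation(a.doc_id, a.start, a.end, label, source_id)
        if model.boundary_jitter > 0 and rng.random() < model.boundary_jitter:
            block = [sp for sp in occupied[a.doc_id] if sp != a.span]
            block += claimed.get(a.doc_id, [])
            ann = _jitter(ann, doc_map[a.doc_id], rng, block)
        claimed.setdefault(a.doc_id, []).append(ann.span)
        kept_by_doc.setdefault(a.doc_id, []).append(ann)
    # spurious spans, never overlapping gold, kept spans, or each other
    for doc_id in sorted(doc_map):
        doc = doc_map[doc_id]
        n_spur = rng.poisson(model.spurious_rate)
        if n_spur == 0:
            continue
        blocked = sorted(set(occupied.get(doc_id, []))
                         | set(claimed.get(doc_id, [])))
        free = [i for i, (s, e) in enumerate(doc.tokens)
                if not any(s < be and bs < e for bs, be in blocked)]
        labels = sorted(model.confusion) or sorted(
            {a.label for a in gold}) or ["PHI"]
        taken: list[tuple[int, int]] = []
        for _ in range(n_spur):
            if not free:
                break
            idx = free[rng.integers(len(free))]
            length = int(rng.integers(1, 3))
            last = min(idx + length - 1, len(doc.tokens) - 1)
            while last > idx and last not in free:
                last -= 1
            span = (doc.tokens[idx][0], doc.tokens[last][1])
            if any(span[0] < te and ts < span[1] for ts, te in taken):
                continue
            taken.append(span)
            free = [i for i in free if not (idx <= i <= last)]
            label = labels[rng.integers(len(labels))]
            kept_by_doc.setdefault(doc_id, []).append(
                Annotation(doc_id, span[0], span[1], label, source_id))
    for doc_id in sorted(kept_by_doc):
        out.extend(sorted(kept_by_doc[doc_id]))
    return AnnotationSet(source_id, out)


def _jitter(ann: Annotation, doc: Document, rng: np.random.Generator,
            blocked: list[tuple[int, int]]) -> Annotation:
    """Shrink or extend the span by one token, keeping it clear of other
    gold spans; returns the annotation unchanged when no move is legal."""
    tokens = doc.tokens
    covered = [i for i, (s, e) in enumerate(tokens)
               if s < ann.end and ann.start < e]
    if not covered:
        return ann
    extend = bool(rng.integers(2))
    left = bool(rng.integers(2))
    if extend:
        if left and covered[0] > 0:
            s, e = tokens[covered[0] - 1]
        elif not left and covered[-1] < len(tokens) - 1:
            s, e = tokens[covered[-1] + 1]
        else:
            return ann
        if any(s < be and bs < e for bs, be in blocked
               if (bs, be) != (ann.start, ann.end)):
            return ann
        new = (min(ann.start, s), max(ann.end, e))
    else:
        if len(covered) < 2:
            return ann
        if left:
            new = (tokens[covered[1]][0], ann.end)
        else:
            new = (ann.start, tokens[covered[-2]][1])
    return replace(ann, start=new[0], end=new[1])


def build_annotation_study(cfg: SynthConfig,
                           models: Sequence[AnnotatorErrorModel] | None = None,
                           ) -> AnnotationStudy:
    """Gold corpus plus one simulated annotation set per error model."""
    if models is None:
        models = default_error_models(cfg.seed)
    if len(models) < 2:
        raise ValueError("a study needs at least two annotator models")
    docs, gold = generate_gold_corpus(cfg)
    sets = [
        simulate_annotator(gold, model, f"annotator{i + 1}", docs)
        for i, model in enumerate(models)
    ]
    return AnnotationStudy(documents=docs, annotator_sets=sets, gold=gold)
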