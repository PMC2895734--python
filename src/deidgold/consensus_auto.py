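"""Automatic consensus gold standard.

Merges several annotators' span sets into one recall-oriented reference:
the union of all annotations is taken, overlapping annotations are
clustered into instances, and each instance is resolved to a single span
and label:

* **span** — the longest member span (de-identification prefers covering
  too much over too little);
* **label** — majority vote first (one vote per annotator); if no strict
  plurality, the most specific label when all candidates sit on one chain
  of the catalog's refinement order (``First_Name`` vs
  ``Clinician_First_Name`` resolves to the latter); otherwise a fixed
  deterministic tie-break order;
* spans annotated by only one annotator (singletons) are kept by default.
"""

from __future__ import annotations

from dataclasses import dataclass

from .corpus_model import (
    Annotation,
    AnnotationSet,
    AnnotationStudy,
    DEFAULT_CATALOG,
    LabelCatalog,
)

__all__ = [
    "OverlapCluster",
    "ResolutionPolicy",
    "cluster_annotations",
    "resolve_span",
    "resolve_label",
    "build_automatic_consensus",
]


@dataclass
class OverlapCluster:
    """A maximal group of annotations pairwise connected by character
    overlap (transitive closure) within one document — one "instance" as
    judged by at least one annotator."""

    doc_id: str
    members: list[Annotation]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("empty cluster")
        self.members = sorted(self.members)

    def sources(self) -> list[str]:
        return sorted({m.source for m in self.members})

    def votes(self) -> dict[str, str]:
        """One label vote per annotator: the label of that annotator's
        longest member (ties: earliest start, then label order)."""
        best: dict[str, Annotation] = {}
        for m in self.members:
            cur = best.get(m.source)
            if cur is None:
                best[m.source] = m
                continue
            key = (-(m.end - m.start), m.start, m.label)
            cur_key = (-(cur.end - cur.start), cur.start, cur.label)
            if key < cur_key:
                best[m.source] = m
        return {src: ann.label for src, ann in sorted(best.items())}


@dataclass(frozen=True)
class ResolutionPolicy:
    """How clusters are resolved into consensus annotations."""

    catalog: LabelCatalog = DEFAULT_CATALOG
    tie_break: tuple[str, ...] | None = None  # None -> lexicographic
    include_singletons: bool = True
    min_overlap: float = 0.0  # fraction of the shorter span; 0 = any overlap

    def tie_rank(self, label: str) -> tuple:
        if self.tie_break is None:
            return (label,)
        try:
            return (self.tie_break.index(label),)
        except ValueError:
            return (len(self.tie_break), label)


def _overlap_edge(a: Annotation, b: Annotation, min_overlap: float) -> bool:
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return False
    if min_overlap <= 0:
        return True
    return ov >= min_overlap * min(a.end - a.start, b.end - b.start)


def cluster_annotations(study: AnnotationStudy,
                        min_overlap: float = 0.0) -> list[OverlapCluster]:
    """Partition the pooled annotations of all annotators into maximal
    connected components under character overlap.

    With the default any-overlap threshold a fast sweep applies (the union
    of a component's spans is contiguous); a positive ``min_overlap``
    fraction falls back to union-find over in-document pairs.
    """
    by_doc: dict[str, list[Annotation]] = {}
    for aset in study.annotator_sets:
        for a in aset:
            by_doc.setdefault(a.doc_id, []).append(a)
    clusters: list[OverlapCluster] = []
    for doc_id in sorted(by_doc):
        anns = sorted(by_doc[doc_id])
        if min_overlap <= 0:
            cur: list[Annotation] = []
            cur_end = -1
            for a in anns:
                if cur and a.start >= cur_end:
                    clusters.append(OverlapCluster(doc_id, cur))
                    cur = []
                cur.append(a)
                cur_end = max(cur_end, a.end)
            if cur:
                clusters.append(OverlapCluster(doc_id, cur))
        else:
            parent = list(range(len(anns)))

            def find(i: int) -> int:
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i in range(len(anns)):
                for j in range(i + 1, len(anns)):
                    if anns[j].start >= anns[i].end:
                        break
                    if _overlap_edge(anns[i], anns[j], min_overlap):
                        parent[find(j)] = find(i)
            groups: dict[int, list[Annotation]] = {}
            for i, a in enumerate(anns):
                groups.setdefault(find(i), []).append(a)
            for root in sorted(groups, key=lambda r: groups[r][0]):
                clusters.append(OverlapCluster(doc_id, groups[root]))
    return clusters


def resolve_span(cluster: OverlapCluster) -> tuple[int, int]:
    """The longest member span; equal lengths resolve to the smallest
    start."""
    best = min(cluster.members,
               key=lambda m: (-(m.end - m.start), m.start))
    return (best.start, best.end)


def resolve_label(cluster: OverlapCluster,
                  policy: ResolutionPolicy | None = None,
                  log: list | None = None) -> str:
    """Majority vote, then specificity, then the deterministic tie-break.

    One vote per annotator (its longest member's label).  A label wins
    outright if it holds a strict plurality of votes.  Failing that, if all
    voted labels are pairwise comparable in the catalog's refinement order
    the most specific one wins.  Otherwise the policy's tie-break order
    decides.  Every decision path can be logged.
    """
    policy = policy or ResolutionPolicy()
    votes = cluster.votes()
    for lab in votes.values():
        if lab not in policy.catalog.labels:
            raise ValueError(f"label {lab!r} outside catalog")
    tally: dict[str, int] = {}
    for lab in votes.values():
        tally[lab] = tally.get(lab, 0) + 1
    ranked = sorted(tally.items(), key=lambda kv: (-kv[1],) + policy.tie_rank(kv[0]))
    label, top = ranked[0]
    how = "unanimous" if len(tally) == 1 else None
    if how is None:
        if top >= 2 and (len(ranked) == 1 or ranked[1][1] < top):
            how = "majority"
        else:
            specific = policy.catalog.most_specific(list(tally))
            if specific is not None:
                label, how = specific, "specificity"
            else:
                label = min(tally, key=policy.tie_rank)
                how = "tie_break"
    if log is not None:
        log.append({"doc_id": cluster.doc_id,
                    "span": resolve_span(cluster),
                    "votes": votes, "label": label, "how": how})
    return label


def build_automatic_consensus(study: AnnotationStudy,
                              policy: ResolutionPolicy | None = None,
                              log: list | None = None) -> AnnotationSet:
    """One consensus annotation per overlap cluster.

    The output is non-overlapping (each resolved span stays within its
    cluster's contiguous extent), has exactly one annotation per retained
    cluster, and keeps single-annotator spans when the policy says so.
    """
    policy = policy or ResolutionPolicy()
    out: list[Annotation] = []
    for cluster in cluster_annotations(study, policy.min_overlap):
        if (not policy.include_singletons
                and len(set(cluster.sources())) < 2):
            continue
        start, end = resolve_span(cluster)
        label = resolve_label(cluster, policy, log)
        out.append(Annotation(cluster.doc_id, start, end, label,
                              "consensus_auto"))
    # with an overlap-fraction threshold, clusters need not have disjoint
    # extents, so resolved spans may legitimately overlap across clusters
    return AnnotationSet("consensus_auto", out,
                         check_overlap=policy.min_overlap <= 0)
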