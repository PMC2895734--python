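"""Inter-annotator agreement as pairwise F-score, plus the agreement
table of annotated instances and their class judgments.

Agreement between two annotators is measured exactly like system
evaluation: one annotator is treated as the reference, the other as the
response, and precision/recall/F follow from the one-to-one span matcher.
F is symmetric in the pair because P(a,b) = R(b,a) and the matcher's
relevant count does not depend on argument order.

The headline "average IAA" is the micro-average over all instances; the
per-class macro view is also available from the underlying reports.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .corpus_model import AnnotationSet, AnnotationStudy
from .consensus_auto import cluster_annotations
from .evaluation import count_matches, compute_prf

__all__ = ["pairwise_iaa", "pairwise_matrix", "mean_pairwise_f",
           "agreement_table"]


def pairwise_iaa(a: AnnotationSet, b: AnnotationSet, mode: str = "exact",
                 docs=None) -> tuple[float, float, float]:
    """(precision, recall, F) of annotator ``b`` against annotator ``a``.

    Returns NaN for all three (with a warning) when both sets are empty —
    agreement is undefined on nothing.
    """
    if len(a) == 0 and len(b) == 0:
        warnings.warn("IAA undefined: both annotation sets are empty")
        return (math.nan, math.nan, math.nan)
    prf = compute_prf(count_matches(a, b, mode, docs).overall)
    return (prf.precision, prf.recall, prf.f_score)


def pairwise_matrix(study: AnnotationStudy,
                    mode: str = "exact") -> pd.DataFrame:
    """Symmetric annotator-by-annotator F-score matrix (diagonal 1).

    The returned frame carries each annotator's total annotation count in
    ``df.attrs["totals"]`` — the totals view the agreement analysis pairs
    with the matrix.
    """
    sources = study.sources()
    docs = study.doc_map
    n = len(sources)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, f = pairwise_iaa(study.annotator_sets[i],
                                   study.annotator_sets[j], mode, docs)
            mat[i, j] = mat[j, i] = f
    df = pd.DataFrame(mat, index=sources, columns=sources)
    df.attrs["totals"] = {s.source: len(s) for s in study.annotator_sets}
    return df


def mean_pairwise_f(study: AnnotationStudy, mode: str = "exact") -> float:
    """Mean off-diagonal pairwise F — the single-number agreement figure."""
    df = pairwise_matrix(study, mode)
    n = len(df)
    vals = [df.iloc[i, j] for i in range(n) for j in range(i + 1, n)]
    return float(np.mean(vals)) if vals else math.nan


def agreement_table(study: AnnotationStudy) -> pd.DataFrame:
    """One row per annotated instance (overlap cluster), one column per
    class holding the number of annotators who judged the instance to be
    of that class.

    Shares the clustering code path with the automatic consensus, so the
    row count always equals the consensus cluster count.  Per-annotator
    totals ride along in ``df.attrs["totals"]``.
    """
    clusters = cluster_annotations(study)
    labels = sorted({m.label for c in clusters for m in c.members})
    rows = []
    for c in clusters:
        votes = c.votes()
        row: dict = {"doc_id": c.doc_id,
                     "start": min(m.start for m in c.members),
                     "end": max(m.end for m in c.members),
                     "n_annotators": len(votes)}
        for lab in labels:
            row[lab] = sum(1 for v in votes.values() if v == lab)
        rows.append(row)
    df = pd.DataFrame(rows,
                      columns=["doc_id", "start", "end", "n_annotators", *labels])
    df.attrs["totals"] = {s.source: len(s) for s in study.annotator_sets}
    return df
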