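"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a result by the most direct method available —
graph search, exhaustive matching, closed forms, plain Monte Carlo — and
deliberately shares no code with the package paths it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching


# ---------------------------------------------------------------------------
# Consensus oracle
# ---------------------------------------------------------------------------

def brute_consensus(annotations_by_source: dict[str, list[tuple]],
                    catalog, include_singletons: bool = True,
                    tie_break=None):
    """Union + overlap clustering + longest-span + majority/specificity
    resolution, recomputed from first principles.

    ``annotations_by_source`` maps source -> list of (doc_id, start, end,
    label).  Returns a sorted list of (doc_id, start, end, label).
    """
    pool = [(doc, s, e, lab, src)
            for src, anns in annotations_by_source.items()
            for (doc, s, e, lab) in anns]
    by_doc: dict[str, list] = {}
    for rec in pool:
        by_doc.setdefault(rec[0], []).append(rec)

    out = []
    for doc in sorted(by_doc):
        recs = by_doc[doc]
        n = len(recs)
        # connected components via BFS on the pairwise-overlap graph
        adj = [[] for _ in range(n)]
        for i in range(n):
            for j in range(i + 1, n):
                if recs[i][1] < recs[j][2] and recs[j][1] < recs[i][2]:
                    adj[i].append(j)
                    adj[j].append(i)
        seen = [False] * n
        for root in range(n):
            if seen[root]:
                continue
            comp = []
            stack = [root]
            seen[root] = True
            while stack:
                i = stack.pop()
                comp.append(recs[i])
                for j in adj[i]:
                    if not seen[j]:
                        seen[j] = True
                        stack.append(j)
            if not include_singletons and len({r[4] for r in comp}) < 2:
                continue
            # longest span, ties to smallest start
            span = sorted(((-(e - s), s, e) for _, s, e, _, _ in comp))[0]
            start, end = span[1], span[2]
            # one vote per source: label of its longest member
            votes = {}
            for src in sorted({r[4] for r in comp}):
                mine = [r for r in comp if r[4] == src]
                mine.sort(key=lambda r: (-(r[2] - r[1]), r[1], r[3]))
                votes[src] = mine[0][3]
            tally: dict[str, int] = {}
            for lab in votes.values():
                tally[lab] = tally.get(lab, 0) + 1
            top = max(tally.values())
            winners = sorted(lab for lab, c in tally.items() if c == top)
            order = (lambda l: (tie_break.index(l),)) if tie_break \
                else (lambda l: (l,))
            if top >= 2 and len(winners) == 1:
                label = winners[0]
            else:
                label = _most_specific(sorted(tally), catalog)
                if label is None:
                    label = min(tally, key=order)
            out.append((doc, start, end, label))
    return sorted(out)


def _most_specific(labels, catalog):
    def chain(l):
        out = [l]
        while out[-1] in catalog.parent:
            out.append(catalog.parent[out[-1]])
        return out

    for cand in labels:
        ch = chain(cand)
        if all(l in ch for l in labels):
            return cand
    return None


# ---------------------------------------------------------------------------
# Matching oracle
# ---------------------------------------------------------------------------

def optimal_relevant(gold: list[tuple], pred: list[tuple], mode: str,
                     tokens_by_doc=None) -> int:
    """Maximum one-to-one matching size via Hopcroft-Karp.

    ``gold``/``pred`` are (doc_id, start, end, label) tuples; ``mode`` is
    ``exact`` (identical span+label, token-snapped when token spans are
    supplied) or ``partial`` (same label, character overlap).
    """
    def key(rec):
        doc, s, e, lab = rec
        if mode == "exact" and tokens_by_doc is not None:
            toks = tokens_by_doc[doc]
            hit = [(ts, te) for ts, te in toks if ts < e and s < te]
            if hit:
                s, e = min(s, hit[0][0]), max(e, hit[-1][1])
        return (doc, s, e, lab)

    rows, cols = [], []
    for i, g in enumerate(gold):
        for j, p in enumerate(pred):
            if g[0] != p[0] or g[3] != p[3]:
                continue
            if mode == "exact":
                ok = key(g)[1:3] == key(p)[1:3]
            else:
                ok = min(g[2], p[2]) - max(g[1], p[1]) > 0
            if ok:
                rows.append(i)
                cols.append(j)
    if not rows:
        return 0
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)),
                       shape=(len(gold), len(pred)))
    match = maximum_bipartite_matching(graph, perm_type="column")
    return int((match >= 0).sum())


# ---------------------------------------------------------------------------
# Annotator-model oracles
# ---------------------------------------------------------------------------

def miss_only_f_expectation(n: int, miss: float, reps: int,
                            seed: int) -> float:
    """Monte-Carlo expectation of the pairwise exact F-score between two
    annotators who independently drop each of ``n`` gold spans with
    probability ``miss`` and change nothing else."""
    rng = np.random.default_rng(seed)
    keep_a = rng.random((reps, n)) >= miss
    keep_b = rng.random((reps, n)) >= miss
    match = (keep_a & keep_b).sum(axis=1)
    denom = keep_a.sum(axis=1) + keep_b.sum(axis=1)
    valid = denom > 0
    return float(np.mean(2 * match[valid] / denom[valid]))


def random_nonoverlapping_spans(rng, n_tokens: int, max_n: int,
                                labels: tuple, token_len: int = 4):
    """Random token-aligned, non-overlapping (start, end, label) char spans
    over a synthetic token grid (token i covers [i*token_len,
    i*token_len + token_len - 1))."""
    n = int(rng.integers(0, max_n + 1))
    starts = rng.permutation(n_tokens)[:n]
    spans = []
    occupied = np.zeros(n_tokens, bool)
    for s in sorted(int(x) for x in starts):
        length = int(rng.integers(1, 3))
        e = min(s + length, n_tokens)
        if occupied[s:e].any():
            continue
        occupied[s:e] = True
        label = str(labels[rng.integers(len(labels))])
        spans.append((s * token_len, e * token_len - 1, label))
    return spans
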