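"""Brute-force reference implementations used only as test oracles.

Deliberately naive and independent of the package internals: plain-python
BFS over adjacency dicts, exhaustive pair counting for AUC, and full
enumeration of degree-matched sets.
"""

from __future__ import annotations

import itertools
from collections import deque


def adjacency(edges):
    adj: dict = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    return adj


def bfs_dists(adj, source):
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in adj.get(u, ()):
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def all_pairs_dists(edges):
    adj = adjacency(edges)
    return {u: bfs_dists(adj, u) for u in adj}


def oracle_closest(edges, S, T):
    """Mean over t in T of min over s in S of d(s, t); unreachable t skipped."""
    ap = all_pairs_dists(edges)
    vals = []
    for t in T:
        ds = [ap[s][t] for s in S if t in ap.get(s, {})]
        if ds:
            vals.append(min(ds))
    return sum(vals) / len(vals)


def oracle_shortest(edges, S, T):
    ap = all_pairs_dists(edges)
    vals = [ap[s][t] for s in S for t in T if t in ap.get(s, {})]
    return sum(vals) / len(vals)


def oracle_lcc_size(edges, restrict):
    """Largest connected component of the subgraph induced on ``restrict``."""
    restrict = set(restrict)
    sub_edges = [(u, v) for u, v in edges if u in restrict and v in restrict]
    adj = adjacency(sub_edges)
    for n in restrict:
        adj.setdefault(n, set())
    seen: set = set()
    best = 0
    for n in restrict:
        if n in seen:
            continue
        comp = set(bfs_dists({k: v & restrict for k, v in adj.items()}, n))
        seen |= comp
        best = max(best, len(comp))
    return best


def oracle_auc(scores, labels):
    """Concordant-pair count with ties worth 0.5, over all pos×neg pairs."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def enumerate_degree_matched(target, bins):
    """All degree-matched node sets for ``target`` (cartesian product of
    within-bin combinations).  Feasible only on toy graphs."""
    counts: dict[int, int] = {}
    for n in target:
        b = bins.bin_of(n)
        counts[b] = counts.get(b, 0) + 1
    per_bin = [
        list(itertools.combinations(bins.bin_members[b], k))
        for b, k in sorted(counts.items())
    ]
    for combo in itertools.product(*per_bin):
        yield set(itertools.chain.from_iterable(combo))
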