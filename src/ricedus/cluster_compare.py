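"""Hierarchical clustering of both distance matrices and their comparison.

Both sides are clustered with UPGMA (average linkage), the prevailing
choice for variety-similarity dendrograms.  Concordance between the
molecular and phenotypic trees is operationalized as shared cherries:
variety pairs that are merged directly as mutual sisters in BOTH trees.

The agglomeration is implemented here (a naive O(N^3) loop — panels are
at most a few hundred varieties) so the tie rule can be fixed exactly:
equal-distance merges pick the candidate pair whose smallest leaf label
is lexicographically least.  scipy's average linkage serves as an
independent cross-check in the test suite.
"""

from __future__ import annotations

import numpy as np

from .containers import Dendrogram, DistanceMatrix


def upgma(dm: DistanceMatrix, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering with average (UPGMA) or complete linkage.

    Heights follow the ultrametric convention: two leaves at distance d
    merge at height d/2.
    """
    if linkage not in ("average", "complete"):
        raise ValueError("linkage must be 'average' or 'complete'")
    n = dm.n
    if n < 2:
        raise ValueError("need at least 2 varieties")
    leaves = list(dm.variety_ids)
    # active cluster id -> (member leaf indices, representative label)
    dist: dict[frozenset[int], float] = {}
    active: dict[int, list[int]] = {i: [i] for i in range(n)}
    rep: dict[int, str] = {i: leaves[i] for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((i, j))] = float(dm.values[i, j])

    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        ids = sorted(active)
        best: tuple[float, str, str, int, int] | None = None
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                d = dist[frozenset((a, b))]
                lo, hi = sorted((rep[a], rep[b]))
                key = (d, lo, hi, a, b)
                if best is None or key < best:
                    best = key
        d, _, _, a, b = best
        # update distances to the new cluster before removing a, b
        na, nb = len(active[a]), len(active[b])
        new_members = active[a] + active[b]
        for c in active:
            if c in (a, b):
                continue
            dac = dist[frozenset((a, c))]
            dbc = dist[frozenset((b, c))]
            if linkage == "average":
                dist[frozenset((next_id, c))] = (na * dac + nb * dbc) / (
                    na + nb
                )
            else:
                dist[frozenset((next_id, c))] = max(dac, dbc)
        del active[a], active[b]
        active[next_id] = new_members
        rep[next_id] = min(rep[a], rep[b])
        merges.append((a, b, d / 2.0))
        next_id += 1
    # enforce nondecreasing heights (UPGMA guarantees this up to float noise)
    for k in range(1, len(merges)):
        a, b, h = merges[k]
        merges[k] = (a, b, max(h, merges[k - 1][2]))
    return Dendrogram(leaves=leaves, merges=merges)


def merge_heights(t: Dendrogram) -> dict[int, float]:
    """Ultrametric height of every cluster id (leaves at height 0)."""
    heights = {i: 0.0 for i in range(t.n_leaves)}
    for k, (_, _, h) in enumerate(t.merges):
        heights[t.n_leaves + k] = h
    return heights


def to_newick(t: Dendrogram) -> str:
    """Newick text with ultrametric branch lengths.

    Child ordering is deterministic: the subtree whose smallest leaf
    label sorts first is written first.
    """
    heights = merge_heights(t)
    children: dict[int, tuple[int, int]] = {
        t.n_leaves + k: (a, b) for k, (a, b, _) in enumerate(t.merges)
    }

    def min_leaf(node: int) -> str:
        if node < t.n_leaves:
            return t.leaves[node]
        a, b = children[node]
        return min(min_leaf(a), min_leaf(b))

    def render(node: int, parent_height: float) -> str:
        branch = parent_height - heights[node]
        if node < t.n_leaves:
            return f"{t.leaves[node]}:{branch:.10g}"
        a, b = children[node]
        if min_leaf(a) > min_leaf(b):
            a, b = b, a
        inner = f"({render(a, heights[node])},{render(b, heights[node])})"
        return f"{inner}:{branch:.10g}"

    root = t.n_leaves + len(t.merges) - 1
    a, b = children[root]
    if min_leaf(a) > min_leaf(b):
        a, b = b, a
    h = heights[root]
    return f"({render(a, h)},{render(b, h)});"


def matched_sister_pairs(t1: Dendrogram, t2: Dendrogram) -> set[frozenset[str]]:
    """Variety pairs that form a cherry (mutual sisters) in both trees."""
    if set(t1.leaves) != set(t2.leaves):
        raise ValueError("trees are over different leaf sets")
    return t1.cherries() & t2.cherries()
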