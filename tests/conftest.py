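"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library code paths they check:
betweenness/closeness are recomputed by explicit enumeration of all
shortest paths, and the hypergeometric tail by counting draws.
"""

from __future__ import annotations

import itertools
from collections import deque
from fractions import Fraction

import networkx as nx
import pytest

from herbnetscreen.models import (
    Category,
    CompoundRecord,
    CompoundTable,
    GeneSet,
    GeneSetCollection,
)


# --------------------------------------------------------------- oracles


def bfs_distances(adj: dict, s) -> dict:
    dist = {s: 0}
    q = deque([s])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def enumerate_shortest_paths(adj: dict, s, t) -> list[tuple]:
    """All shortest s-t paths, by backtracking over the BFS distance field."""
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    paths = []

    def back(node, acc):
        if node == s:
            paths.append(tuple(reversed(acc + [s])))
            return
        for prev in adj[node]:
            if dist.get(prev, -1) == dist[node] - 1:
                back(prev, acc + [node])

    back(t, [])
    return paths


def oracle_betweenness(g: nx.Graph) -> dict:
    """Normalized betweenness via exhaustive shortest-path enumeration.

    Pair dependencies are summed over unordered pairs s != t != v and
    divided by (Nc-1)(Nc-2)/2 with Nc the node's component size.
    """
    adj = {n: set(g.neighbors(n)) for n in g.nodes}
    comp_of = {}
    for comp in nx.connected_components(g):
        for n in comp:
            comp_of[n] = frozenset(comp)
    bc = {n: Fraction(0) for n in g.nodes}
    for s, t in itertools.combinations(g.nodes, 2):
        if comp_of[s] != comp_of[t]:
            continue
        paths = enumerate_shortest_paths(adj, s, t)
        if not paths:
            continue
        sigma = len(paths)
        for v in g.nodes:
            if v in (s, t) or comp_of[v] != comp_of[s]:
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += Fraction(through, sigma)
    out = {}
    for v in g.nodes:
        nc = len(comp_of[v])
        denom = Fraction((nc - 1) * (nc - 2), 2)
        out[v] = float(bc[v] / denom) if denom else 0.0
    return out


def oracle_closeness(g: nx.Graph) -> dict:
    """Closeness = reachable count / sum of distances (0 when isolated)."""
    adj = {n: set(g.neighbors(n)) for n in g.nodes}
    out = {}
    for v in g.nodes:
        dist = bfs_distances(adj, v)
        del dist[v]
        out[v] = len(dist) / sum(dist.values()) if dist else 0.0
    return out


def oracle_hypergeom_tail(k: int, K: int, n: int, N: int) -> Fraction:
    """P[X >= k] by enumerating every size-n draw from an N-ball urn."""
    balls = [1] * K + [0] * (N - K)
    total = 0
    hits = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(balls[i] for i in draw) >= k:
            hits += 1
    return Fraction(hits, total)


# --------------------------------------------------------------- fixtures


@pytest.fixture
def herb_tables() -> list[CompoundTable]:
    """Two herb tables with the study's shape: 65 + 100 compounds, 2 shared."""
    shared = [f"MOL9{i:05d}" for i in range(2)]
    fuzi = CompoundTable(
        [CompoundRecord(c, f"c{c}", frozenset({"fuzi"})) for c in shared]
        + [
            CompoundRecord(f"MOL1{i:05d}", f"f{i}", frozenset({"fuzi"}))
            for i in range(63)
        ]
    )
    rougui = CompoundTable(
        [CompoundRecord(c, f"c{c}", frozenset({"rougui"})) for c in shared]
        + [
            CompoundRecord(f"MOL2{i:05d}", f"r{i}", frozenset({"rougui"}))
            for i in range(98)
        ]
    )
    return [fuzi, rougui]


@pytest.fixture
def disease_collection() -> GeneSetCollection:
    return GeneSetCollection(
        [
            GeneSet("stroke", "d", Category.DISEASE, frozenset({"T1", "T2"})),
            GeneSet("thrombosis", "d", Category.DISEASE, frozenset({"T2", "T3"})),
        ]
    )
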