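"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — all-pairs BFS, neighbor-pair
triple enumeration, explicit Pearson sums, exhaustive enumeration of
hypergeometric draws — and shares no code with the package internals.
"""

from __future__ import annotations

import itertools
import math
from collections import deque
from fractions import Fraction

import networkx as nx


def bfs_distances(g: nx.Graph, source) -> dict:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in g.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def components_by_bfs(g: nx.Graph) -> list[set]:
    seen: set = set()
    comps = []
    for node in g.nodes:
        if node in seen:
            continue
        comp = set(bfs_distances(g, node))
        seen |= comp
        comps.append(comp)
    return comps


def oracle_measures(g: nx.Graph) -> dict:
    """All graph measures by brute force on a loop-free simple graph."""
    n = g.number_of_nodes()
    m = g.number_of_edges()
    comps = components_by_bfs(g)
    largest = max(comps, key=len)
    diameter = 0
    if len(largest) > 1:
        sub = g.subgraph(largest)
        diameter = max(
            max(bfs_distances(sub, s).values()) for s in sub.nodes
        )

    # average local clustering, triple enumeration, degree < 2 contributes 0
    total = 0.0
    for v in g.nodes:
        nbrs = list(g.neighbors(v))
        d = len(nbrs)
        if d < 2:
            continue
        closed = sum(
            1 for u, w in itertools.combinations(nbrs, 2) if g.has_edge(u, w)
        )
        total += 2.0 * closed / (d * (d - 1))
    clustering = total / n

    # assortativity: explicit Pearson over endpoint degrees, both orientations
    deg = dict(g.degree)
    xs, ys = [], []
    for a, b in g.edges:
        xs += [deg[a], deg[b]]
        ys += [deg[b], deg[a]]
    assortativity = None
    if xs:
        k = len(xs)
        mx = sum(xs) / k
        my = sum(ys) / k
        vx = sum((x - mx) ** 2 for x in xs)
        vy = sum((y - my) ** 2 for y in ys)
        if vx > 0 and vy > 0:
            cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
            assortativity = cov / math.sqrt(vx * vy)

    return {
        "n_nodes": n,
        "n_edges": m,
        "mean_degree": 2.0 * m / n,
        "diameter": diameter,
        "index_of_aggregation": len(largest) / n,
        "connectivity": 2.0 * m / (n * (n - 1)) if n > 1 else 0.0,
        "clustering_coefficient": clustering,
        "assortativity": assortativity,
        "n_components": len(comps),
    }


def hypergeom_upper_tail_by_enumeration(N: int, K: int, n: int, k: int) -> Fraction:
    """P(overlap >= k) by enumerating every n-subset of an N-universe."""
    annotated = set(range(K))
    hits = 0
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(annotated.intersection(draw)) >= k:
            hits += 1
    return Fraction(hits, total)
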