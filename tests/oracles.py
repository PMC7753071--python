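"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately naive — exhaustive BFS shortest-path
enumeration, recursive simple-path search, exact rational arithmetic —
and shares no code with the implementation it checks.
"""

from collections import deque
from fractions import Fraction
from itertools import combinations
from math import comb


def bfs_all_shortest_paths(adj, source):
    """All shortest paths from source as {target: [path, ...]}."""
    dist = {source: 0}
    paths = {source: [[source]]}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in sorted(adj[u]):
            if v not in dist:
                dist[v] = dist[u] + 1
                paths[v] = [p + [v] for p in paths[u]]
                queue.append(v)
            elif dist[v] == dist[u] + 1:
                paths[v].extend(p + [v] for p in paths[u])
    return dist, paths


def oracle_centralities(adj):
    """Degree, normalized betweenness, WF closeness, clustering per node.

    adj: {node: set(neighbors)} for a simple undirected graph.
    """
    nodes = sorted(adj)
    n = len(nodes)
    degree = {v: float(len(adj[v])) for v in nodes}

    # betweenness: enumerate every shortest path between every pair
    bet = {v: Fraction(0) for v in nodes}
    all_sp = {s: bfs_all_shortest_paths(adj, s) for s in nodes}
    for s, t in combinations(nodes, 2):
        dist, paths = all_sp[s]
        if t not in dist:
            continue
        st_paths = paths[t]
        total = len(st_paths)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in st_paths if v in p)
            bet[v] += Fraction(through, total)
    norm = Fraction((n - 1) * (n - 2), 2) if n > 2 else Fraction(1)
    betweenness = {v: float(bet[v] / norm) for v in nodes}

    # closeness, Wasserman-Faust component scaling
    closeness = {}
    for v in nodes:
        dist, _ = all_sp[v]
        reachable = len(dist) - 1
        total = sum(dist.values())
        if reachable == 0 or total == 0:
            closeness[v] = 0.0
        else:
            closeness[v] = float(
                Fraction(reachable, total) * Fraction(reachable, n - 1)
            )

    clustering = {}
    for v in nodes:
        k = len(adj[v])
        if k < 2:
            clustering[v] = 0.0
            continue
        links = sum(
            1 for a, b in combinations(sorted(adj[v]), 2) if b in adj[a]
        )
        clustering[v] = float(Fraction(2 * links, k * (k - 1)))

    return degree, betweenness, closeness, clustering


def oracle_hypergeom_point(a, b, c, d):
    """Eq.-style single-table probability with exact rationals."""
    return Fraction(comb(b, a) * comb(d, c), comb(b + d, a + c))


def oracle_hypergeom_tail(a, b, c, d):
    """P[overlap >= a] by explicit summation over all tables."""
    total = Fraction(0)
    for k in range(a, min(b, c) + 1):
        if b - k > d - c:
            continue
        total += Fraction(comb(c, k) * comb(d - c, b - k), comb(d, b))
    return total


def oracle_simple_paths(adj, sources, targets, max_edges):
    """All simple paths source->target with <= max_edges edges.

    Recursive depth-first search; returns a set of node tuples.
    """
    targets = set(targets)
    found = set()

    def walk(path):
        tail = path[-1]
        if len(path) >= 2 and tail in targets:
            found.add(tuple(path))
        if len(path) > max_edges:
            return
        for nxt in adj.get(tail, ()):
            if nxt not in path:
                walk(path + [nxt])

    for s in sources:
        walk([s])
    return found
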