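"""Independent brute-force oracles used only by the tests.

Everything here is deliberately naive — explicit enumeration, exact rational
arithmetic, Floyd-Warshall with full path listing — and shares no code with
the implementation it checks.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np

INF = float("inf")


def oracle_centralities(edges: list[tuple], nodes: list) -> dict:
    """All four centralities + clustering by exhaustive path enumeration.

    Returns {node: {"degree", "closeness", "betweenness", "eccentricity",
    "clustering"}} with clustering None for degree < 2.
    """
    nodes = list(nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    adj = [set() for _ in range(n)]
    for a, b in edges:
        if a == b:
            continue
        adj[idx[a]].add(idx[b])
        adj[idx[b]].add(idx[a])
    D = [[INF] * n for _ in range(n)]
    for i in range(n):
        D[i][i] = 0
        for j in adj[i]:
            D[i][j] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i][k] + D[k][j] < D[i][j]:
                    D[i][j] = D[i][k] + D[k][j]

    def all_shortest_paths(s, t):
        if s == t:
            return [[s]]
        out = []
        for nb in adj[s]:
            if D[nb][t] == D[s][t] - 1:
                out += [[s] + p for p in all_shortest_paths(nb, t)]
        return out

    # connected components
    comp = [-1] * n
    cid = 0
    for i in range(n):
        if comp[i] == -1:
            stack = [i]
            while stack:
                u = stack.pop()
                if comp[u] == -1:
                    comp[u] = cid
                    stack.extend(adj[u])
            cid += 1
    comp_size = [comp.count(c) for c in range(cid)]

    betweenness = [0.0] * n
    for s, t in itertools.combinations(range(n), 2):
        if D[s][t] == INF:
            continue
        paths = all_shortest_paths(s, t)
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            if through:
                betweenness[v] += through / len(paths)
    result = {}
    for i, v in enumerate(nodes):
        others = [D[i][j] for j in range(n) if j != i and D[i][j] < INF]
        closeness = len(others) / sum(others) if others and sum(others) else 0.0
        ecc = max(others) if others else 0
        k = len(adj[i])
        if k < 2:
            clust = None
        else:
            among = sum(1 for x, y in itertools.combinations(adj[i], 2) if y in adj[x])
            clust = among / (k * (k - 1) / 2)
        nc = comp_size[comp[i]]
        norm = (nc - 1) * (nc - 2) / 2
        result[v] = {
            "degree": k,
            "closeness": closeness,
            "betweenness": betweenness[i] / norm if norm > 0 else 0.0,
            "eccentricity": ecc,
            "clustering": clust,
        }
    return result


def mw_exact_two_sided(a, b) -> float:
    """Two-sided exact Mann-Whitney p by enumerating every rank assignment.

    Requires tie-free pooled samples.
    """
    a = list(a)
    b = list(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires no ties"
    na = len(a)
    u_obs = sum(1 for x in a for y in b if x > y)
    mu = na * len(b) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), na):
        sel = set(combo)
        u = sum(1 for i in sel for j in range(len(pooled)) if j not in sel and i > j)
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


def fisher_two_sided(table) -> float:
    """Two-sided Fisher p by full enumeration of margin-fixed tables."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    N = r1 + r2

    def prob(x) -> Fraction:
        if not (0 <= x <= r1 and 0 <= c1 - x <= r2):
            return Fraction(0)
        return Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), math.comb(N, c1))

    p_obs = prob(a)
    total = sum(prob(x) for x in range(0, min(r1, c1) + 1)
                if prob(x) <= p_obs * Fraction(1 + 10**-9))
    return float(total)


def midranks(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    ranks = np.empty(len(x))
    order = np.argsort(x, kind="stable")
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def spearman_midrank(x, y) -> float:
    """Spearman rho as the Pearson correlation of midranks, from scratch."""
    rx = midranks(x)
    ry = midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))


def hypergeom_tail_fraction(observed, category, query, universe) -> Fraction:
    """Exact upper-tail hypergeometric probability as a rational number."""
    total = math.comb(universe, query)
    tail = sum(
        math.comb(category, k) * math.comb(universe - category, query - k)
        for k in range(observed, min(category, query) + 1))
    return Fraction(tail, total)


def random_connected_graph(rng: np.random.Generator, max_nodes: int = 8):
    """A random connected simple graph with 2..max_nodes nodes."""
    while True:
        n = int(rng.integers(2, max_nodes + 1))
        p = float(rng.uniform(0.25, 0.9))
        edges = [(i, j) for i, j in itertools.combinations(range(n), 2)
                 if rng.random() < p]
        if not edges:
            continue
        # connectivity check
        adj = {i: set() for i in range(n)}
        for a, b in edges:
            adj[a].add(b)
            adj[b].add(a)
        seen = {0}
        stack = [0]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        if len(seen) == n:
            return n, edges
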