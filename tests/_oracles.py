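"""Independent brute-force oracles used by the test suite.

Everything here is computed from first principles on adjacency dicts —
exhaustive path enumeration, Floyd-Warshall distances, power iteration,
direct triangle counting — deliberately avoiding the code paths (and the
graph library) used by the implementation under test.
"""

from __future__ import annotations

import itertools
from fractions import Fraction


def adjacency(n_nodes: int, edges) -> dict:
    adj = {v: set() for v in range(n_nodes)}
    for a, b in edges:
        if a != b:
            adj[a].add(b)
            adj[b].add(a)
    return adj


def floyd_warshall(adj: dict) -> dict:
    nodes = list(adj)
    inf = float("inf")
    d = {u: {v: (0 if u == v else (1 if v in adj[u] else inf)) for v in nodes}
         for u in nodes}
    for k in nodes:
        for i in nodes:
            for j in nodes:
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return d


def _all_paths(adj: dict, s, t):
    """All simple paths s -> t by exhaustive DFS."""
    stack = [(s, [s])]
    while stack:
        v, path = stack.pop()
        if v == t:
            yield path
            continue
        for w in adj[v]:
            if w not in path:
                stack.append((w, path + [w]))


def brute_betweenness(adj: dict) -> dict:
    """Raw betweenness by enumerating every shortest path of every pair."""
    d = floyd_warshall(adj)
    bc = {v: Fraction(0) for v in adj}
    for s, t in itertools.combinations(adj, 2):
        if d[s][t] == float("inf"):
            continue
        shortest = [p for p in _all_paths(adj, s, t) if len(p) - 1 == d[s][t]]
        sigma = len(shortest)
        for v in adj:
            if v in (s, t):
                continue
            through = sum(1 for p in shortest if v in p)
            if through:
                bc[v] += Fraction(through, sigma)
    return {v: float(b) for v, b in bc.items()}


def brute_closeness(adj: dict) -> dict:
    """(n_c - 1) / sum of distances within the node's component."""
    d = floyd_warshall(adj)
    cc = {}
    for v in adj:
        comp = [u for u in adj if d[v][u] != float("inf")]
        if len(comp) == 1:
            cc[v] = 0.0
        else:
            cc[v] = (len(comp) - 1) / sum(d[v][u] for u in comp)
    return cc


def _components(adj: dict) -> list:
    seen, comps = set(), []
    for v in adj:
        if v in seen:
            continue
        comp, stack = set(), [v]
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(adj[u] - comp)
        seen |= comp
        comps.append(comp)
    return comps


def brute_eigenvector(adj: dict) -> dict:
    """Shifted power iteration on the largest component (ties: min node)."""
    comps = sorted(_components(adj), key=lambda c: (-len(c), min(str(v) for v in c)))
    comp = sorted(comps[0])
    ec = {v: 0.0 for v in adj}
    if len(comp) == 1:
        ec[comp[0]] = 1.0
        return ec
    x = {v: 1.0 for v in comp}
    for _ in range(200000):
        # (A + I) x  — the shift guarantees convergence on bipartite graphs
        y = {v: x[v] + sum(x[w] for w in adj[v] if w in x) for v in comp}
        norm = sum(val * val for val in y.values()) ** 0.5
        y = {v: val / norm for v, val in y.items()}
        if max(abs(y[v] - x[v]) for v in comp) < 1e-14:
            x = y
            break
        x = y
    ec.update(x)
    return ec


def brute_lac(adj: dict) -> dict:
    """Mean within-neighborhood degree, straight from the definition."""
    lac = {}
    for v, nbrs in adj.items():
        if not nbrs:
            lac[v] = 0.0
            continue
        lac[v] = sum(len(adj[w] & nbrs) for w in nbrs) / len(nbrs)
    return lac


def brute_nc(adj: dict) -> dict:
    """Sum of edge clustering coefficients, by direct triangle counting."""
    nc = {}
    for v, nbrs in adj.items():
        total = Fraction(0)
        for w in nbrs:
            denom = min(len(adj[v]) - 1, len(adj[w]) - 1)
            if denom > 0:
                total += Fraction(len(adj[v] & adj[w]), denom)
        nc[v] = float(total)
    return nc


def hypergeom_upper_enum(N: int, K: int, n: int, k: int) -> Fraction:
    """P(X >= k) by exact combinatorial enumeration."""
    from math import comb

    total = comb(N, n)
    favourable = sum(
        comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1)
    )
    return Fraction(favourable, total)


def bh_stepup_naive(pvalues):
    """Literal BH step-up: sort, scale, running minimum from the right."""
    m = len(pvalues)
    indexed = sorted(range(m), key=lambda i: pvalues[i])
    scaled = [pvalues[indexed[i]] * m / (i + 1) for i in range(m)]
    adjusted = [0.0] * m
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, scaled[i])
        adjusted[indexed[i]] = min(running, 1.0)
    return adjusted
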