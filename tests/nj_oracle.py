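"""Independent oracle for neighbor-joining checks.

Enumerates every unrooted binary topology on n leaves (3, 15, 105, 945,
10395 for n = 4..8), fits branch lengths to a distance matrix by ordinary
least squares on the pair-path incidence system, and returns the topology
with the smallest residual.  For an additive matrix the generating topology
has residual zero and is the unique optimum when internal branches are
positive.  Nothing here touches the package's NJ implementation.
"""

from __future__ import annotations

from collections import deque

import numpy as np

_CACHE: dict[int, list] = {}


def _enumerate_adjacency(n: int) -> list[dict[int, list[int]]]:
    """All unrooted binary tree shapes with leaves 0..n-1 (internal nodes
    numbered from n upward), built by inserting leaves into every edge."""
    base = {0: [n], 1: [n], 2: [n], n: [0, 1, 2]}
    trees = [base]
    for leaf in range(3, n):
        grown = []
        for adj in trees:
            edges = {
                tuple(sorted((u, v))) for u, vs in adj.items() for v in vs
            }
            new_node = max(adj) + 1
            for u, v in sorted(edges):
                t = {k: list(vs) for k, vs in adj.items()}
                t[u].remove(v)
                t[v].remove(u)
                t[u].append(new_node)
                t[v].append(new_node)
                t[new_node] = [u, v, leaf]
                t[leaf] = [new_node]
                grown.append(t)
        trees = grown
    return trees


def _edges(adj) -> list[tuple[int, int]]:
    return sorted({tuple(sorted((u, v))) for u, vs in adj.items() for v in vs})


def _path_edges(adj, a: int, b: int) -> list[tuple[int, int]]:
    prev = {a: None}
    q = deque([a])
    while q:
        u = q.popleft()
        if u == b:
            break
        for v in adj[u]:
            if v not in prev:
                prev[v] = u
                q.append(v)
    path = []
    node = b
    while prev[node] is not None:
        path.append(tuple(sorted((node, prev[node]))))
        node = prev[node]
    return path


def _incidence(adj, n: int) -> np.ndarray:
    edges = _edges(adj)
    index = {e: k for k, e in enumerate(edges)}
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    a = np.zeros((len(pairs), len(edges)))
    for row, (i, j) in enumerate(pairs):
        for e in _path_edges(adj, i, j):
            a[row, index[e]] = 1.0
    return a


def _bipartitions(adj, n: int) -> frozenset:
    """Non-trivial splits as frozensets of leaf indices, canonicalized to
    the side not containing leaf 0."""
    splits = set()
    for u, v in _edges(adj):
        if len(adj[u]) == 1 or len(adj[v]) == 1:
            continue
        # leaves on v's side when the (u, v) edge is cut
        seen = {u, v}
        q = deque([v])
        side = set()
        while q:
            x = q.popleft()
            if len(adj[x]) == 1:
                side.add(x)
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    q.append(y)
        if 0 in side:
            side = set(range(n)) - side
        if 2 <= len(side) <= n - 2:
            splits.add(frozenset(side))
    return frozenset(splits)


def topology_bank(n: int) -> list:
    """Cached (adjacency, splits, Q1, incidence) per topology for n leaves."""
    if n not in _CACHE:
        bank = []
        for adj in _enumerate_adjacency(n):
            a = _incidence(adj, n)
            q1, _ = np.linalg.qr(a)
            bank.append((adj, _bipartitions(adj, n), q1, a))
        _CACHE[n] = bank
    return _CACHE[n]


def pair_vector(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    return np.array([d[i, j] for i in range(n) for j in range(i + 1, n)])


def least_squares_topology(d: np.ndarray) -> frozenset:
    """Splits of the OLS-optimal topology for distance matrix ``d``."""
    n = d.shape[0]
    vec = pair_vector(d)
    total = vec @ vec
    best = None
    best_resid = np.inf
    for adj, splits, q1, _ in topology_bank(n):
        resid = total - np.sum((q1.T @ vec) ** 2)
        if resid < best_resid:
            best_resid = resid
            best = splits
    return best


def random_additive(n: int, rng: np.random.Generator):
    """(distance matrix, splits) from a random topology with branch lengths
    uniform in [0.1, 1.0] — internal branches strictly positive."""
    bank = topology_bank(n)
    adj, splits, _, incidence = bank[rng.integers(0, len(bank))]
    lengths = rng.uniform(0.1, 1.0, size=incidence.shape[1])
    vec = incidence @ lengths
    d = np.zeros((n, n))
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = vec[k]
            k += 1
    return d, splits
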