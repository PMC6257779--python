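"""Independent brute-force oracles for graph statistics.

Everything here is deliberately naive — dense Floyd–Warshall distances,
exhaustive simple-path enumeration for geodesic counts, explicit triple
enumeration — so it shares no code path with the package implementations
it cross-checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def floyd_warshall(n: int, edges: set[tuple[int, int]]) -> np.ndarray:
    """Dense all-pairs shortest directed path lengths (inf if unreachable)."""
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i, j in edges:
        d[i, j] = 1.0
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    return d


def path_stats(n: int, edges: set[tuple[int, int]]) -> tuple[float, float, float]:
    """(diameter, average path length, global efficiency) by brute force."""
    d = floyd_warshall(n, edges)
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(d)
    if not finite.any() or n < 2:
        return 0.0, 0.0, 0.0
    dia = float(d[finite].max())
    avg = float(d[finite].mean())
    eff = float(np.sum(1.0 / d[finite])) / (n * (n - 1))
    return dia, avg, eff


def betweenness_by_enumeration(n: int, edges: set[tuple[int, int]]) -> list[float]:
    """B_v = sum over ordered pairs of the geodesic fraction through v,
    with geodesics found by enumerating *all* simple paths."""
    adj = {i: [j for (a, j) in edges if a == i] for i in range(n)}

    def all_simple_paths(src: int, dst: int):
        stack = [(src, [src])]
        while stack:
            node, path = stack.pop()
            if node == dst:
                yield path
                continue
            for nxt in adj[node]:
                if nxt not in path:
                    stack.append((nxt, path + [nxt]))

    b = [0.0] * n
    for i, j in itertools.permutations(range(n), 2):
        paths = list(all_simple_paths(i, j))
        if not paths:
            continue
        dmin = min(len(p) for p in paths)
        geos = [p for p in paths if len(p) == dmin]
        for v in range(n):
            if v in (i, j):
                continue
            through = sum(1 for p in geos if v in p[1:-1])
            b[v] += through / len(geos)
    return b


def transitivity_by_enumeration(n: int, edges: set[tuple[int, int]]) -> float:
    """3 * triangles / connected triples on the undirected projection."""
    und = {frozenset(e) for e in edges if e[0] != e[1]}
    triangles = 0
    for a, b, c in itertools.combinations(range(n), 3):
        if (
            frozenset((a, b)) in und
            and frozenset((b, c)) in und
            and frozenset((a, c)) in und
        ):
            triangles += 1
    deg = [sum(1 for e in und if v in e) for v in range(n)]
    triples = sum(math.comb(d, 2) for d in deg)
    return 3 * triangles / triples if triples else 0.0


def max_vulnerability_by_recomputation(n: int, edges: set[tuple[int, int]]) -> float:
    """max_i (E - E_i)/E, recomputing efficiency on each node-deleted graph."""
    _, _, e_full = path_stats(n, edges)
    if e_full == 0.0:
        return 0.0
    worst = -np.inf
    for v in range(n):
        keep = [u for u in range(n) if u != v]
        relabel = {u: k for k, u in enumerate(keep)}
        sub = {(relabel[i], relabel[j]) for (i, j) in edges if i != v and j != v}
        _, _, e_v = path_stats(n - 1, sub)
        worst = max(worst, (e_full - e_v) / e_full)
    return float(worst)


def random_digraph(rng: np.random.Generator, n_max: int = 8, p_edge: float = 0.3):
    """(n, edge set) with no self-loops, for oracle cross-checks."""
    n = int(rng.integers(2, n_max + 1))
    edges = {
        (i, j)
        for i in range(n)
        for j in range(n)
        if i != j and rng.random() < p_edge
    }
    return n, edges
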