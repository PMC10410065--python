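"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive — literal definitions, enumeration,
matrix powers — and shares no code with the package under test.
"""

from __future__ import annotations

import math

import numpy as np


def bh_stepup(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values by the literal step-up rule."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by direct pmf summation with exact integer combinatorics."""
    denom = math.comb(N, n)
    total = 0
    for x in range(k, min(K, n) + 1):
        if n - x <= N - K:
            total += math.comb(K, x) * math.comb(N - K, n - x)
    return total / denom


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities <= observed's."""
    r1, r2 = a + b, c + d
    c1 = a + c
    N = r1 + r2
    denom = math.comb(N, c1)

    def prob(x: int) -> float:
        return math.comb(r1, x) * math.comb(r2, c1 - x) / denom

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def bfs_levels_matrix(nodes: list[str], edges: list[tuple[str, str]],
                      sources: set[str], max_level: int) -> dict[str, int]:
    """Shortest-path depth from a source set via boolean adjacency powers."""
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n), dtype=bool)
    for a, b in edges:
        adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = True
    reach = np.zeros(n, dtype=bool)
    for s in sources:
        if s in idx:
            reach[idx[s]] = True
    depth = {nodes[i]: 0 for i in range(n) if reach[i]}
    frontier = reach.copy()
    seen = reach.copy()
    for d in range(1, max_level + 1):
        frontier = adj[frontier].any(axis=0) & ~seen
        for i in np.flatnonzero(frontier):
            depth[nodes[i]] = d
        seen |= frontier
    return depth


def greedy_clump(snps: list[str], pvals: dict[str, float],
                 r2: dict[tuple[str, str], float],
                 pos: dict[str, tuple[str, int]],
                 r2_max: float, window_bp: int) -> list[str]:
    """Literal greedy clumping definition."""

    def rsq(x: str, y: str) -> float:
        if x == y:
            return 1.0
        return r2.get((x, y), r2.get((y, x), 0.0))

    accepted: list[str] = []
    for s in sorted(set(snps), key=lambda s: (pvals[s], s)):
        ok = True
        for a in accepted:
            same_chrom = pos[s][0] == pos[a][0]
            close = same_chrom and abs(pos[s][1] - pos[a][1]) <= window_bp
            if close and rsq(s, a) >= r2_max:
                ok = False
        if ok:
            accepted.append(s)
    return accepted


def transitive_components(snps: list[str], linked) -> list[set[str]]:
    """Connected components by repeated closure of a pairwise link predicate."""
    comps: list[set[str]] = []
    for s in snps:
        merged = {s}
        rest = []
        for comp in comps:
            if any(linked(s, t) or s == t for t in comp):
                merged |= comp
            else:
                rest.append(comp)
        comps = rest + [merged]
    # repeat until stable (single pass can miss chains created by later merges)
    changed = True
    while changed:
        changed = False
        for i in range(len(comps)):
            for j in range(i + 1, len(comps)):
                if any(linked(x, y) for x in comps[i] for y in comps[j]):
                    comps[i] |= comps[j]
                    del comps[j]
                    changed = True
                    break
            if changed:
                break
    return comps
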