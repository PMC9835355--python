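"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: plain reachability by DFS, repeated full scans in
shuffled order, big-integer combinatorics — no shared code paths with
the package internals they verify.
"""

from __future__ import annotations

import random
from math import comb


def reachable_from(adj: dict[str, set[str]], start: str) -> set[str]:
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in adj.get(u, ()):
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return seen


def brute_force_seed_compounds(nodes: list[str], edges: list[tuple[str, str]]) -> set[str]:
    """Nodes whose SCC is not reachable from any other SCC (source components).

    A node u is a seed iff every node that reaches u is also reached by u
    (i.e. nothing outside u's SCC reaches it).
    """
    adj: dict[str, set[str]] = {n: set() for n in nodes}
    for s, t in edges:
        adj[s].add(t)
    reach = {n: reachable_from(adj, n) for n in nodes}
    seeds = set()
    for u in nodes:
        if all(u not in reach[v] or v in reach[u] for v in nodes):
            seeds.add(u)
    return seeds


def naive_expansion_scope(
    reactions: list[tuple[str, list[str], list[str], bool]],
    seeds: set[str],
    rng: random.Random,
) -> tuple[set[str], set[str]]:
    """Repeated full scans in a shuffled reaction order until fixed point.

    ``reactions``: (id, substrates, products, reversible) tuples.
    Returns (scope, fired reaction ids).
    """
    directed = []
    for rid, subs, prods, rev in reactions:
        directed.append((rid, set(subs), set(prods)))
        if rev:
            directed.append((rid, set(prods), set(subs)))
    rng.shuffle(directed)
    scope = set(seeds)
    fired: set[str] = set()
    changed = True
    while changed:
        changed = False
        for rid, subs, prods in directed:
            if subs <= scope:
                fired.add(rid)
                if not prods <= scope:
                    scope |= prods
                    changed = True
    return scope, fired


def hypergeom_tail_exact(k: int, N: int, K: int, n: int):
    """Upper-tail hypergeometric as an exact fraction via big-int binomials."""
    from fractions import Fraction

    num = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1))
    return Fraction(num, comb(N, n))


def bh_reject(pvals: list[float], alpha: float) -> set[int]:
    """Indices rejected by the textbook Benjamini-Hochberg step-up procedure."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    kmax = 0
    for rank, i in enumerate(order, start=1):
        if pvals[i] <= rank * alpha / m:
            kmax = rank
    return set(order[:kmax])
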