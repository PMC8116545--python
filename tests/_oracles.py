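"""Independent brute-force oracles used to validate the statistical machinery.

Everything here is deliberately naive — exhaustive enumeration, exact
rational arithmetic, explicit path counting — and shares no code with the
implementation under test.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration.

    Sums the probabilities of every table with the observed margins whose
    probability does not exceed the observed table's (with the conventional
    1 + 1e-7 relative tie tolerance).
    """
    r1 = a + b
    c1 = a + c
    n = a + b + c + d
    denom = comb(n, r1)
    lo = max(0, r1 - (n - c1))
    hi = min(r1, c1)
    probs = {
        x: comb(c1, x) * comb(n - c1, r1 - x) / denom for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7))


def hypergeom_upper_tail_exact(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X hypergeometric(N, K, n), via exact rational sums."""
    total = Fraction(0)
    denom = comb(N, n)
    for x in range(max(k, 0, n - (N - K)), min(K, n) + 1):
        total += Fraction(comb(K, x) * comb(N - K, n - x), denom)
    return float(total)


def _all_shortest_paths(adj: dict, s, t) -> list[list]:
    """Enumerate every shortest s-t path by BFS levels + backward DFS."""
    from collections import deque

    dist = {s: 0}
    q = deque([s])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    if t not in dist:
        return []
    paths = []

    def back(v, acc):
        if v == s:
            paths.append([s] + acc)
            return
        for u in adj[v]:
            if dist.get(u) == dist[v] - 1:
                back(u, [v] + acc)

    back(t, [])
    return paths


def betweenness_oracle(adj: dict) -> dict:
    """Unnormalized betweenness: for each unordered pair, the fraction of
    shortest paths passing through each interior vertex, summed."""
    nodes = sorted(adj)
    bc = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            paths = _all_shortest_paths(adj, s, t)
            if not paths:
                continue
            for p in paths:
                for v in p[1:-1]:
                    bc[v] += 1.0 / len(paths)
    return bc


def clustering_oracle(adj: dict) -> dict:
    """Local clustering coefficient: connected neighbor pairs / possible pairs."""
    out = {}
    for v, nbrs in adj.items():
        nbrs = sorted(nbrs)
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(
            1
            for i in range(k)
            for j in range(i + 1, k)
            if nbrs[j] in adj[nbrs[i]]
        )
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def bh_oracle(pvals: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up by the textbook recursion."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvals[i] / rank)
        q_sorted[rank - 1] = running
    out = [0.0] * m
    for rank, i in enumerate(order):
        out[i] = q_sorted[rank]
    return out
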