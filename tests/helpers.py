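"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths (and the libraries
behind them): the hypergeometric tail is obtained by enumerating every
possible draw, and betweenness by enumerating every shortest path.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations


def enumerate_tail_distribution(K: int, n: int, N: int) -> dict[int, Fraction]:
    """P(X >= k) for all k, by enumerating every size-n draw from N.

    The first K universe elements are the 'annotated' ones. Returns a map
    k -> exact tail probability.
    """
    successes = set(range(K))
    counts: dict[int, int] = {}
    total = 0
    for draw in combinations(range(N), n):
        c = sum(1 for x in draw if x in successes)
        counts[c] = counts.get(c, 0) + 1
        total += 1
    tails: dict[int, Fraction] = {}
    running = 0
    for k in range(min(K, n), -1, -1):
        running += counts.get(k, 0)
        tails[k] = Fraction(running, total)
    return tails


def enumerate_hypergeometric_tail(k: int, K: int, n: int, N: int) -> Fraction:
    """Exact P(X >= k) by exhaustive enumeration of draws."""
    return enumerate_tail_distribution(K, n, N)[k]


def brute_force_betweenness(nodes: list, edges: list[tuple]) -> dict:
    """Freeman betweenness by explicit enumeration of all shortest paths.

    Undirected, unnormalized, endpoints excluded, each unordered pair
    counted once; disconnected pairs contribute nothing.
    """
    adj: dict = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    btw = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        # BFS distances from s
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if w not in dist:
                        dist[w] = dist[u] + 1
                        nxt.append(w)
            frontier = nxt
        if t not in dist:
            continue
        # walk backwards from t along strictly decreasing distance,
        # collecting every shortest path
        paths: list[tuple] = []

        def _walk(v, acc):
            if v == s:
                paths.append(tuple(acc))
                return
            for w in adj[v]:
                if w in dist and dist[w] == dist[v] - 1:
                    _walk(w, acc + [w])

        _walk(t, [t])
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            btw[v] += through / len(paths)
    return btw
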