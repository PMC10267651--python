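"""Independent brute-force oracles for the graph quantities under test.

Everything here is deliberately naive — exhaustive path enumeration,
triple loops, direct definitions — and shares no code with the package, so
agreement is evidence rather than tautology.  Only usable for tiny graphs.
"""

from __future__ import annotations

import numpy as np


def random_weighted_graph(rng, n_nodes, p_edge=0.5, ensure_edge=True):
    """Random symmetric weighted matrix with lognormal-ish weights."""
    w = np.zeros((n_nodes, n_nodes))
    iu = np.triu_indices(n_nodes, k=1)
    present = rng.random(len(iu[0])) < p_edge
    if ensure_edge and not present.any():
        present[rng.integers(len(present))] = True
    vals = np.exp(rng.normal(0, 0.8, len(iu[0])))
    w[iu[0][present], iu[1][present]] = vals[present]
    return w + w.T


def floyd_warshall_lengths(w):
    """All-pairs shortest path lengths with length = 1/weight."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_apl(w):
    """Mean shortest-path length to reachable targets; NaN if none."""
    d = floyd_warshall_lengths(w)
    n = w.shape[0]
    out = np.empty(n)
    for i in range(n):
        vals = [d[i, j] for j in range(n) if j != i and np.isfinite(d[i, j])]
        out[i] = np.mean(vals) if vals else np.nan
    return out


def _all_simple_paths(w, s, t):
    n = w.shape[0]
    paths = []
    stack = [(s, [s], 0.0)]
    while stack:
        node, path, length = stack.pop()
        if node == t:
            paths.append((path, length))
            continue
        for nxt in range(n):
            if w[node, nxt] > 0 and nxt not in path:
                stack.append((nxt, path + [nxt], length + 1.0 / w[node, nxt]))
    return paths


def brute_betweenness(w, tol=1e-10):
    """Exhaustive shortest-path counting; endpoints excluded, each
    unordered pair counted once, fractional credit for tied paths."""
    n = w.shape[0]
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = _all_simple_paths(w, s, t)
            if not paths:
                continue
            best = min(length for _, length in paths)
            shortest = [p for p, length in paths if length <= best * (1 + tol) + tol]
            sigma = len(shortest)
            for p in shortest:
                for v in p[1:-1]:
                    bc[v] += 1.0 / sigma
    return bc


def brute_clustering(w):
    """Onnela weighted clustering via an explicit ordered-triple loop."""
    n = w.shape[0]
    wmax = w.max()
    cc = np.zeros(n)
    if wmax == 0:
        return cc
    wh = w / wmax
    for i in range(n):
        k = int((w[i] > 0).sum())
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for h in range(n):
                if j == i or h == i or j == h:
                    continue
                if w[i, j] > 0 and w[i, h] > 0 and w[j, h] > 0:
                    total += (wh[i, j] * wh[i, h] * wh[j, h]) ** (1.0 / 3.0)
        cc[i] = total / (k * (k - 1))
    return cc


def brute_phi(w, k):
    """Weighted rich-club coefficient straight from its definition."""
    n = w.shape[0]
    deg = [(w[i] > 0).sum() for i in range(n)]
    rich = [i for i in range(n) if deg[i] > k]
    if len(rich) < 2:
        return np.nan
    inside = []
    for a in range(len(rich)):
        for b in range(a + 1, len(rich)):
            if w[rich[a], rich[b]] > 0:
                inside.append(w[rich[a], rich[b]])
    if not inside:
        return np.nan
    all_w = sorted(
        (w[i, j] for i in range(n) for j in range(i + 1, n) if w[i, j] > 0), reverse=True
    )
    return sum(inside) / sum(all_w[: len(inside)])


def unweighted_bfs_apl(adj):
    """Hop-count APL for a binary graph (oracle for the binary special case)."""
    n = adj.shape[0]
    out = np.empty(n)
    for s in range(n):
        dist = {s: 0}
        frontier = [s]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in range(n):
                    if adj[u, v] and v not in dist:
                        dist[v] = d
                        nxt.append(v)
            frontier = nxt
        vals = [dd for node, dd in dist.items() if node != s]
        out[s] = np.mean(vals) if vals else np.nan
    return out


def pearson(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return float(np.corrcoef(x, y)[0, 1])


def partial_corr_formula(x, y, z):
    """Textbook first-order partial correlation from pairwise Pearson r."""
    rxy, rxz, ryz = pearson(x, y), pearson(x, z), pearson(y, z)
    return (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
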