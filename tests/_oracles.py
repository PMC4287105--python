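"""Independent brute-force oracles used by the test suite.

Every oracle here re-derives its quantity from first principles (ordinary
least squares, exhaustive enumeration, direct formulas) so that it shares
no code path with the implementation it checks.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
from scipy import linalg


def ols_anova_f(y: np.ndarray, cells: np.ndarray) -> tuple[float, int, int]:
    """Classical two-way ANOVA-with-interaction F via cell-means OLS.

    ``cells`` assigns each observation to one age x genotype cell; the full
    model is the cell-means model, the reduced model the grand mean.
    """
    y = np.asarray(y, float)
    levels = sorted(set(cells))
    X = np.column_stack([(cells == c).astype(float) for c in levels])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss_full = float(np.sum((y - X @ beta) ** 2))
    rss_red = float(np.sum((y - y.mean()) ** 2))
    p = len(levels)
    dfn, dfd = p - 1, len(y) - p
    return ((rss_red - rss_full) / dfn) / (rss_full / dfd), dfn, dfd


def dense_grid_profile_loglik(y: np.ndarray, X: np.ndarray, ZZt: np.ndarray,
                              coarse: int = 400, fine: int = 4001) -> float:
    """Max profile ML log-likelihood over the variance ratio by dense grids.

    Direct computation with the marginal covariance ``V = I + gamma ZZ'``
    (Cholesky solves, no eigen-rotation): a coarse log grid locates the
    optimum, a dense local grid pins it down.
    """
    y = np.asarray(y, float)
    n = len(y)

    def loglik(gamma: float) -> float:
        V = np.eye(n) + gamma * ZZt
        c, low = linalg.cho_factor(V)
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        Vy = linalg.cho_solve((c, low), y)
        VX = linalg.cho_solve((c, low), X)
        beta = np.linalg.solve(X.T @ VX, X.T @ Vy)
        r = y - X @ beta
        rss = float(r @ linalg.cho_solve((c, low), r))
        s2 = rss / n
        return float(-0.5 * n * (np.log(2 * np.pi * s2) + 1.0) - 0.5 * logdet)

    grid = np.concatenate([[0.0], np.geomspace(1e-7, 1e5, coarse)])
    lls = np.array([loglik(g) for g in grid])
    i = int(np.argmax(lls))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    local = np.linspace(lo, hi, fine)
    return max(lls[i], max(loglik(g) for g in local))


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the textbook step-up rule."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def hypergeom_upper_tail_enum(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) by exhaustive enumeration of all size-n draws from N."""
    marked = set(range(K))
    hits = sum(
        1 for draw in itertools.combinations(range(N), n) if len(marked & set(draw)) >= k
    )
    return hits / comb(N, n)


def hypergeom_upper_tail_comb(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) by direct combinatorial summation."""
    total = comb(N, n)
    return sum(
        comb(K, j) * comb(N - K, n - j)
        for j in range(k, min(n, K) + 1)
        if n - j <= N - K
    ) / total


def betweenness_by_path_enumeration(edges, nodes) -> dict:
    """Unnormalized betweenness by enumerating all shortest paths (BFS DAG)."""
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    btw = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        # BFS from s
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
        paths: list[tuple] = []

        def extend(path):
            u = path[-1]
            if u == t:
                paths.append(path)
                return
            for w in adj[u]:
                if w in dist and dist[w] == dist[u] + 1 and dist[w] <= dist[t]:
                    extend(path + (w,))

        extend((s,))
        if not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                btw[v] += 1.0 / len(paths)
    return btw


def connected_components_unionfind(edges, nodes) -> list[set]:
    """Connected components via union-find."""
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    comps: dict = {}
    for v in nodes:
        comps.setdefault(find(v), set()).add(v)
    return list(comps.values())


def set_partitions(items):
    """All partitions of a list (restricted-growth enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for p in set_partitions(rest):
        for i in range(len(p)):
            yield p[:i] + [[first] + p[i]] + p[i + 1 :]
        yield [[first]] + p


def modularity_direct(edges, partition) -> float:
    """Newman Q from edge lists and a partition, by direct counting."""
    edges = list(edges)
    m = len(edges)
    if m == 0:
        return 0.0
    q = 0.0
    for comm in partition:
        comm = set(comm)
        inside = sum(1 for u, v in edges if u in comm and v in comm)
        ends = sum((u in comm) + (v in comm) for u, v in edges)
        q += inside / m - (ends / (2.0 * m)) ** 2
    return q


def exhaustive_max_modularity(edges, nodes) -> tuple[float, list]:
    """Globally optimal modularity partition by exhaustive search."""
    best_q, best_p = -1.0, None
    for p in set_partitions(list(nodes)):
        q = modularity_direct(edges, p)
        if q > best_q:
            best_q, best_p = q, p
    return best_q, best_p


def ddct_ratio(ct_t_cal, ct_t_s, ct_r_cal, ct_r_s) -> float:
    """Classical 2^(-ddCt) relative quantification."""
    ddct = (ct_t_s - ct_t_cal) - (ct_r_s - ct_r_cal)
    return 2.0 ** (-ddct)
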