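"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles — plain Python loops, BFS by
hand, exhaustive enumeration — deliberately avoiding the code paths (networkx
metric functions, scipy shortest paths, statsmodels adjustments) that the
package itself uses.  Intended for graphs of a few dozen nodes at most.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations
from math import comb, inf


def bfs_distances(adj: dict, source) -> dict:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def graph_to_adj(graph) -> dict:
    return {u: sorted(graph.neighbors(u)) for u in graph.nodes()}


def bf_edge_count(adj: dict) -> int:
    return sum(len(vs) for vs in adj.values()) // 2


def bf_largest_component(adj: dict) -> int:
    seen, best = set(), 0
    for start in adj:
        if start in seen:
            continue
        comp = set(bfs_distances(adj, start))
        seen |= comp
        best = max(best, len(comp))
    return best


def bf_closeness_wf(adj: dict) -> float:
    """Mean Wasserman–Faust closeness ((r-1)/(n-1)) * ((r-1)/sum_d)."""
    n = len(adj)
    total = 0.0
    for v in adj:
        d = bfs_distances(adj, v)
        r = len(d)
        sum_d = sum(d.values())
        if sum_d > 0 and n > 1:
            total += ((r - 1) / (n - 1)) * ((r - 1) / sum_d)
    return total / n


def bf_mean_shortest_distance(adj: dict) -> float:
    dists = []
    for u, v in combinations(sorted(adj), 2):
        d = bfs_distances(adj, u)
        if v in d:
            dists.append(d[v])
    return sum(dists) / len(dists) if dists else float("nan")


def bf_clustering(adj: dict) -> float:
    total = 0.0
    for v, nbrs in adj.items():
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(1 for a, b in combinations(nbrs, 2) if b in adj[a])
        total += links / comb(k, 2)
    return total / len(adj)


def bf_betweenness(adj: dict) -> float:
    """Mean normalized betweenness via explicit shortest-path enumeration."""
    nodes = sorted(adj)
    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        d = bfs_distances(adj, s)
        if t not in d:
            continue
        paths: list[list] = []

        def extend(path):
            last = path[-1]
            if last == t:
                paths.append(path)
                return
            for w in adj[last]:
                if w in d and d[w] == d[last] + 1 and d[w] <= d[t]:
                    extend(path + [w])

        extend([s])
        for p in paths:
            for v in p[1:-1]:
                score[v] += 1 / len(paths)
    if n < 3:
        return 0.0
    norm = (n - 1) * (n - 2) / 2
    return sum(score.values()) / norm / n


def bf_nearest_module_distance(adj: dict, set_a, set_b, self_zero: bool = True) -> float:
    """Nearest-member d_AB by double-loop BFS (other-member rule when A == B)."""
    set_a, set_b = list(set_a), list(set_b)
    equal = set(set_a) == set(set_b)
    exclude = (not self_zero) or equal
    terms = []
    for a in set_a:
        d = bfs_distances(adj, a)
        cands = [d[b] for b in set_b if b in d and not (exclude and b == a)]
        if cands:
            terms.append(min(cands))
    for b in set_b:
        d = bfs_distances(adj, b)
        cands = [d[a] for a in set_a if a in d and not (exclude and a == b)]
        if cands:
            terms.append(min(cands))
    return sum(terms) / len(terms) if terms else 0.0


def bf_within_distance(adj: dict, members) -> float:
    members = list(members)
    terms = []
    for a in members:
        d = bfs_distances(adj, a)
        cands = [d[m] for m in members if m != a and m in d]
        if cands:
            terms.append(min(cands))
    return sum(terms) / len(terms) if terms else 0.0


def hypergeom_pmf(a: int, row1: int, col1: int, n: int) -> float:
    """P(table[0,0] = a | margins) for a 2x2 table with total n."""
    if not (max(0, row1 + col1 - n) <= a <= min(row1, col1)):
        return 0.0
    return comb(col1, a) * comb(n - col1, row1 - a) / comb(n, row1)


def bf_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided exact p by enumerating all tables with the observed margins,
    summing those whose point probability does not exceed the observed one
    (with the 1 + 1e-7 relative slack R and scipy both use)."""
    row1, col1, n = a + b, a + c, a + b + c + d
    p_obs = hypergeom_pmf(a, row1, col1, n)
    total = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p_x = hypergeom_pmf(x, row1, col1, n)
        if p_x <= p_obs * (1 + 1e-7):
            total += p_x
    return min(1.0, total)


def bf_bh(pvals: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up straight from the definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, pvals[i] * m / rank)
        adj[i] = running_min
    return adj


def bf_specificity(expr_rows: dict, cell_types: dict) -> dict:
    """Two-loop specificity: expr_rows[gene][cell] -> proportion per type."""
    types = sorted(set(cell_types.values()))
    out = {}
    for gene, row in expr_rows.items():
        means = {}
        for t in types:
            cells = [c for c in row if cell_types[c] == t]
            means[t] = sum(row[c] for c in cells) / len(cells)
        total = sum(means.values())
        if total == 0:
            continue
        out[gene] = {t: means[t] / total for t in types}
    return out
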