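"""Independent brute-force reference implementations used as test oracles.

Everything here works directly on (formula_id, ordered herb-name list)
records with plain Python loops — no position matrices, no vectorisation —
so it shares no code path with the package implementation it checks.
"""

import math
from collections import deque

from scipy import stats


def brute_pair_stats(records, x, y, mi_form="pmi", score_form="ratio"):
    """All pair statistics for herbs named x, y over raw formula records."""
    m = len(records)
    n_x = n_y = n_xy = 0
    distances = []
    for _, herbs in records:
        has_x, has_y = x in herbs, y in herbs
        n_x += has_x
        n_y += has_y
        if has_x and has_y:
            n_xy += 1
            k = len(herbs)
            bx = (herbs.index(x) + 1) / k
            by = (herbs.index(y) + 1) / k
            distances.append(abs(bx - by))
    p_x, p_y, p_xy = n_x / m, n_y / m, n_xy / m
    if mi_form == "pmi":
        mi = 0.0 if n_xy == 0 else p_xy * math.log2(p_xy / (p_x * p_y))
    else:
        mi = 0.0
        for c, pr, pc in [
            (n_xy, p_x, p_y),
            (n_x - n_xy, p_x, 1 - p_y),
            (n_y - n_xy, 1 - p_x, p_y),
            (m - n_x - n_y + n_xy, 1 - p_x, 1 - p_y),
        ]:
            if c > 0:
                mi += (c / m) * math.log2((c / m) / (pr * pc))
    d_bar = sum(distances) / len(distances) if distances else None
    if d_bar is not None:
        score = mi / d_bar if score_form == "ratio" else mi * (1 - d_bar)
    else:
        score = None
    # textbook chi-square: m (ad - bc)^2 / (r1 r2 c1 c2)
    a, b, c, d = n_xy, n_x - n_xy, n_y - n_xy, m - n_x - n_y + n_xy
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if min(margins) == 0:
        chi2, p_value = 0.0, 1.0
    else:
        chi2 = m * (a * d - b * c) ** 2 / math.prod(margins)
        p_value = float(stats.chi2.sf(chi2, 1))
    return {
        "n_x": n_x, "n_y": n_y, "n_xy": n_xy, "m": m,
        "mi": mi, "d_bar": d_bar, "score": score,
        "chi2": chi2, "p_value": p_value,
    }


def bfs_distances(adjacency, source):
    """Unweighted shortest-path lengths from source via plain BFS."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adjacency[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def brute_mean_shortest_path(edges, nodes, set_a, set_b):
    """Mean cross-pair shortest path and coverage via per-node BFS.

    Returns (None, 0.0) when no cross pair is connected.
    """
    adjacency = {v: set() for v in nodes}
    for u, v in edges:
        adjacency[u].add(v)
        adjacency[v].add(u)
    A = [g for g in set_a if g in adjacency]
    B = [g for g in set_b if g in adjacency]
    total = connected = 0
    acc = 0
    for a in A:
        dist = bfs_distances(adjacency, a)
        for b in B:
            if b == a:
                continue
            total += 1
            if b in dist:
                connected += 1
                acc += dist[b]
    if connected == 0:
        return None, 0.0
    return acc / connected, connected / total


def hypergeom_upper_tail(N, K, n, k):
    """P(X >= k) for a hypergeometric draw, by direct summation."""
    total = 0.0
    for j in range(k, min(K, n) + 1):
        total += math.comb(K, j) * math.comb(N - K, n - j)
    return total / math.comb(N, n)
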