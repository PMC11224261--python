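"""Independent brute-force oracles for graph and FDR computations.

Everything here is deliberately naive — exhaustive path enumeration, direct
formula evaluation, full partition search — and shares no code with the
package implementations it checks. Only usable on tiny inputs.
"""

from __future__ import annotations

import math
from itertools import combinations, permutations

import numpy as np


def pearson(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))


# ---------------------------------------------------------------------------
# exhaustive shortest paths on small weighted graphs
# a graph is a dict: {"nodes": [...], "edges": {(u, v): weight}} with u < v


def edge_length(g, u, v):
    w = g["edges"].get((u, v), g["edges"].get((v, u)))
    return None if w is None else 1.0 / w


def all_simple_paths(g, s, t):
    nodes = g["nodes"]
    out = []

    def extend(path):
        last = path[-1]
        if last == t:
            out.append(list(path))
            return
        for n in nodes:
            if n not in path and edge_length(g, last, n) is not None:
                extend(path + [n])

    extend([s])
    return out


def path_length(g, path):
    return sum(edge_length(g, path[i], path[i + 1]) for i in range(len(path) - 1))


def shortest_paths(g, s, t):
    """(min length, list of minimal paths); (inf, []) if unreachable."""
    paths = all_simple_paths(g, s, t)
    if not paths:
        return math.inf, []
    lengths = [path_length(g, p) for p in paths]
    best = min(lengths)
    minimal = [p for p, l in zip(paths, lengths) if l <= best + 1e-12]
    return best, minimal


def betweenness(g):
    """Unnormalized weighted betweenness by full shortest-path enumeration."""
    out = {n: 0.0 for n in g["nodes"]}
    for s, t in combinations(g["nodes"], 2):
        _, minimal = shortest_paths(g, s, t)
        if not minimal:
            continue
        for n in g["nodes"]:
            if n in (s, t):
                continue
            frac = sum(1 for p in minimal if n in p) / len(minimal)
            out[n] += frac
    return out


def closeness(g):
    """1 / mean shortest-path length to reachable nodes (0 if isolated)."""
    out = {}
    for n in g["nodes"]:
        dists = []
        for m in g["nodes"]:
            if m == n:
                continue
            d, _ = shortest_paths(g, n, m)
            if d < math.inf:
                dists.append(d)
        out[n] = (1.0 / (sum(dists) / len(dists))) if dists else 0.0
    return out


def clustering(g):
    """Triad-counting clustering coefficient on the unweighted topology."""
    def connected(u, v):
        return edge_length(g, u, v) is not None

    out = {}
    for n in g["nodes"]:
        nbrs = [m for m in g["nodes"] if m != n and connected(n, m)]
        k = len(nbrs)
        if k < 2:
            out[n] = 0.0
            continue
        links = sum(1 for u, v in combinations(nbrs, 2) if connected(u, v))
        out[n] = links / (k * (k - 1) / 2)
    return out


def global_efficiency(g):
    n = len(g["nodes"])
    if n < 2:
        return 0.0
    total = 0.0
    for s, t in combinations(g["nodes"], 2):
        d, _ = shortest_paths(g, s, t)
        if d < math.inf and d > 0:
            total += 2.0 / d
    return total / (n * (n - 1))


def local_efficiency(g):
    def connected(u, v):
        return edge_length(g, u, v) is not None

    effs = []
    for n in g["nodes"]:
        nbrs = [m for m in g["nodes"] if m != n and connected(n, m)]
        if len(nbrs) < 2:
            effs.append(0.0)
            continue
        sub = {
            "nodes": nbrs,
            "edges": {
                (u, v): w
                for (u, v), w in g["edges"].items()
                if u in nbrs and v in nbrs
            },
        }
        effs.append(global_efficiency(sub))
    return sum(effs) / len(effs)


# ---------------------------------------------------------------------------
# modularity


def modularity(g, membership):
    """Direct evaluation of Q = sum_c [W_c/W - (S_c/2W)^2]."""
    w_total = sum(g["edges"].values())
    if w_total == 0:
        return 0.0
    comms = set(membership.values())
    q = 0.0
    for c in comms:
        members = {n for n, cc in membership.items() if cc == c}
        w_in = sum(w for (u, v), w in g["edges"].items() if u in members and v in members)
        s = sum(w for (u, v), w in g["edges"].items() if u in members) + sum(
            w for (u, v), w in g["edges"].items() if v in members
        )
        q += w_in / w_total - (s / (2 * w_total)) ** 2
    return q


def set_partitions(items):
    """All partitions of a list into non-empty blocks."""
    if len(items) == 1:
        yield [[items[0]]]
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def max_modularity(g):
    """(best Q, best partition) by exhaustive search over all partitions."""
    best_q, best_p = -math.inf, None
    for part in set_partitions(list(g["nodes"])):
        membership = {n: i for i, block in enumerate(part) for n in block}
        q = modularity(g, membership)
        if q > best_q:
            best_q, best_p = q, part
    return best_q, best_p


# ---------------------------------------------------------------------------
# BH step-up


def bh_stepup(p):
    """Textbook step-up: adj_i = min over j with p_j >= p_i of p_j * m / rank_j."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    running = math.inf
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running = min(running, p[i] * m / (pos + 1))
        adj[i] = min(1.0, running)
    return adj


def graph_from_nx(nxg):
    """Convert a networkx graph to the plain dict format used here."""
    return {
        "nodes": list(nxg.nodes),
        "edges": {(u, v): d["weight"] for u, v, d in nxg.edges(data=True)},
    }
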