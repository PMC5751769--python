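"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the defining formulas with plain loops
and no reuse of the package's computational paths.
"""

from __future__ import annotations

import math

import networkx as nx


def merge_oracle(values: list[float]) -> float:
    """Complement geometric mean, plain arithmetic."""
    prod = 1.0
    for s in values:
        prod *= 1.0 - s
    return 1.0 - prod ** (1.0 / len(values))


def ecc_oracle(g: nx.Graph, x, y) -> float:
    """Triangles through the edge over the maximum possible, by enumeration."""
    z = sum(1 for node in g if node not in (x, y) and g.has_edge(x, node) and g.has_edge(y, node))
    denom = min(g.degree(x) - 1, g.degree(y) - 1)
    return z / denom if denom > 0 else 0.0


def _w(g: nx.Graph, a, b) -> float:
    return g[a][b].get("weight", 1.0)


def _strength(g: nx.Graph, z) -> float:
    return sum(_w(g, z, nb) for nb in g[z])


def index_oracle(g: nx.Graph, x, y, index: str, alpha: float = 0.5) -> float:
    """One of the nine weighted similarity indices by direct enumeration."""
    common = [z for z in g if z not in (x, y) and g.has_edge(x, z) and g.has_edge(y, z)]
    total = 0.0
    for z in common:
        add = _w(g, x, z) + _w(g, z, y)
        mul = _w(g, x, z) * _w(g, z, y)
        sz = _strength(g, z)
        if index == "WCN":
            total += add
        elif index == "WRA":
            total += add / sz if sz > 0 else 0.0
        elif index == "WAA":
            total += add / math.log(1 + sz) if sz > 0 and math.log(1 + sz) > 0 else 0.0
        elif index in ("rWCN", "rWCNLP"):
            total += mul
        elif index in ("rWRA", "rWRALP"):
            total += mul / sz if sz > 0 else 0.0
        elif index in ("rWAA", "rWAALP"):
            total += mul / math.log(1 + sz) if sz > 0 and math.log(1 + sz) > 0 else 0.0
        else:
            raise ValueError(index)
    if index in ("rWCNLP", "rWRALP", "rWAALP"):
        lp = 0.0
        for m in g[x]:
            for n in g[y]:
                if m == n or m == y or n == x:
                    continue  # simple length-3 paths only
                if g.has_edge(m, n):
                    lp += _w(g, x, m) * _w(g, m, n) * _w(g, n, y)
        total += alpha * lp
    return total


def bfs_distances(g: nx.Graph, src) -> dict:
    """Plain queue-based BFS."""
    dist = {src: 0}
    queue = [src]
    while queue:
        node = queue.pop(0)
        for nb in g[node]:
            if nb not in dist:
                dist[nb] = dist[node] + 1
                queue.append(nb)
    return dist


def topology_oracle(g: nx.Graph) -> dict:
    """All Table-1 style metrics from scratch (all-pairs BFS, triple counts)."""
    n = g.number_of_nodes()
    m = g.number_of_edges()
    degs = [g.degree(v) for v in g]
    density = 2.0 * m / (n * (n - 1)) if n > 1 else 0.0
    mean_deg = sum(degs) / n
    var_deg = sum((d - mean_deg) ** 2 for d in degs) / n
    het = math.sqrt(var_deg) / mean_deg if mean_deg > 0 else 0.0
    central = (n / (n - 2.0)) * (max(degs) / (n - 1.0) - density) if n > 2 else 0.0
    ccs = []
    for v in g:
        nbrs = list(g[v])
        k = len(nbrs)
        if k < 2:
            ccs.append(0.0)
            continue
        links = sum(
            1 for i in range(k) for j in range(i + 1, k) if g.has_edge(nbrs[i], nbrs[j])
        )
        ccs.append(2.0 * links / (k * (k - 1)))
    # path metrics on the largest component
    seen, comps = set(), []
    for v in g:
        if v not in seen:
            comp = set(bfs_distances(g, v))
            comps.append(comp)
            seen |= comp
    comps.sort(key=lambda c: (-len(c), min(c)))
    work = g.subgraph(comps[0])
    total, count, eccs = 0, 0, []
    for v in work:
        dist = bfs_distances(work, v)
        ecc = 0
        for u, d in dist.items():
            if u != v:
                total += d
                count += 1
                ecc = max(ecc, d)
        eccs.append(ecc)
    return {
        "n_nodes": n,
        "n_edges": m,
        "cluster_coefficient": sum(ccs) / n,
        "diameter": max(eccs) if eccs else 0,
        "radius": min(eccs) if eccs else 0,
        "centralization": central,
        "n_shortest_paths": count,
        "characteristic_path_length": total / count if count else 0.0,
        "avg_neighbors": 2.0 * m / n,
        "density": density,
        "heterogeneity": het,
    }


def evaluate_oracle(predicted: dict, reference: dict, threshold: float, strict: bool = False):
    """Complex-level precision/recall/F by exhaustive double loop."""

    def jac(a, b):
        return len(a & b) / len(a | b)

    def passes(s):
        return s > threshold if strict else s >= threshold

    matched_pred = sum(
        1 for k in predicted.values() if any(passes(jac(set(k), set(r))) for r in reference.values())
    )
    matched_ref = sum(
        1 for r in reference.values() if any(passes(jac(set(k), set(r))) for k in predicted.values())
    )
    prec = matched_pred / len(predicted)
    rec = matched_ref / len(reference)
    f = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
    return prec, rec, f
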