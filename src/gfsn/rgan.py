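"""The referenced gene-gene association network (RGAN).

Built from integrated PPI data in three steps:

1. every PPI edge (x, y) is reweighted by its edge clustering
   coefficient, ECC(x, y) = z_xy / min(d_x - 1, d_y - 1), where z_xy is
   the number of triangles through the edge — a [0, 1] reliability score
   (0 by convention when the denominator vanishes);
2. nine weighted topological similarity indices are computed on the
   ECC-weighted graph: additive common-neighbour scores (WCN, WRA, WAA),
   their reliable-route multiplicative variants (rWCN, rWRA, rWAA), and
   quasi-local variants adding alpha-weighted simple length-3 path terms
   (rWCNLP, rWRALP, rWAALP);
3. the nine score tables are combined with fixed weights (1/9 each by
   default) into one similarity matrix comparable with IGFSN values.

Scores are stored sparsely: only pairs within three hops can have a
nonzero score, all others are identically zero by the formulas.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from collections.abc import Sequence

import networkx as nx
import numpy as np

from .core import SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = ["RganConfig", "INDEX_NAMES", "integrate_ppi", "ecc_weights", "topo_index", "build_rgan"]

INDEX_NAMES = ("WCN", "WRA", "WAA", "rWCN", "rWRA", "rWAA", "rWCNLP", "rWRALP", "rWAALP")

PairTable = dict[tuple[str, str], float]


@dataclasses.dataclass
class RganConfig:
    """Knobs for the RGAN construction.

    alpha_path
        Weight of the length-3 path term in the quasi-local indices
        (0.5 balances the longer routes against direct common
        neighbours).
    index_weights
        Convex weights over the nine indices in :data:`INDEX_NAMES`
        order; 1/9 each by default.
    normalize
        ``"max"`` divides each index table by its maximum positive score
        before combination (scores become comparable with [0, 1]
        similarities), ``"rank"`` maps scores to normalised ranks,
        ``"none"`` combines raw scores.
    lp_only_unconnected
        If True, the length-3 path term is zeroed on adjacent pairs, so
        quasi-local indices only extend coverage to unconnected genes.
    """

    alpha_path: float = 0.5
    index_weights: Sequence[float] = tuple([1.0 / 9.0] * 9)
    normalize: str = "max"
    lp_only_unconnected: bool = False

    def __post_init__(self) -> None:
        if self.alpha_path < 0:
            raise ValueError("alpha_path must be >= 0")
        if len(self.index_weights) != 9 or any(w < 0 for w in self.index_weights):
            raise ValueError("index_weights must be nine non-negative reals")
        if self.normalize not in {"max", "none", "rank"}:
            raise ValueError(f"unknown normalize mode {self.normalize!r}")


def integrate_ppi(networks: Sequence[nx.Graph], gene_universe: set[str] | None = None) -> nx.Graph:
    """Union of PPI edge sets, restricted to a gene universe.

    The output is unweighted (weight 1 per edge): provenance counts do
    not enter the association model, reliability is assessed afterwards
    by :func:`ecc_weights`.
    """
    if not networks:
        raise ValueError("need at least one network")
    out = nx.Graph()
    if gene_universe is not None:
        out.add_nodes_from(sorted(gene_universe))
    for net in networks:
        for u, v in net.edges:
            if gene_universe is None or (u in gene_universe and v in gene_universe):
                out.add_edge(u, v, weight=1.0)
    if out.number_of_edges() == 0:
        raise ValueError("integrated PPI network has no edges within the gene universe")
    return out


def ecc_weights(net: nx.Graph) -> nx.Graph:
    """Reweight every edge by its edge clustering coefficient.

    The edge set is unchanged; input weights are ignored (ECC is a
    purely topological reliability score in [0, 1]).
    """
    out = net.copy()
    for x, y in out.edges:
        dx, dy = out.degree(x), out.degree(y)
        denom = min(dx - 1, dy - 1)
        if denom <= 0:
            ecc = 0.0
        else:
            z = len(set(out[x]) & set(out[y]))
            ecc = z / denom
        out[x][y]["weight"] = ecc
    return out


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _compute_index_tables(net: nx.Graph, config: RganConfig) -> dict[str, PairTable]:
    """All nine score tables in one pass over the weighted graph.

    Common-neighbour sums are accumulated per hub z over its neighbour
    pairs; length-3 path sums per edge (m, n) over neighbour pairs
    (x in G(m), y in G(n)), excluding degenerate walks (m = y, n = x,
    m = n), i.e. simple paths only.
    """
    w = {_pair_key(u, v): d.get("weight", 1.0) for u, v, d in net.edges(data=True)}
    strength = {z: sum(net[z][nb].get("weight", 1.0) for nb in net[z]) for z in net}
    tables: dict[str, PairTable] = {name: {} for name in INDEX_NAMES}

    def bump(table: PairTable, key: tuple[str, str], val: float) -> None:
        if val != 0.0:
            table[key] = table.get(key, 0.0) + val

    n_zero_strength = 0
    for z in net:
        nbrs = sorted(net[z])
        sz = strength[z]
        if sz == 0.0 and len(nbrs) >= 2:
            n_zero_strength += 1
        log_sz = math.log1p(sz)
        for i, x in enumerate(nbrs):
            wxz = w[_pair_key(x, z)]
            for y in nbrs[i + 1:]:
                wzy = w[_pair_key(z, y)]
                key = _pair_key(x, y)
                add, mul = wxz + wzy, wxz * wzy
                bump(tables["WCN"], key, add)
                bump(tables["rWCN"], key, mul)
                if sz > 0.0:
                    bump(tables["WRA"], key, add / sz)
                    bump(tables["rWRA"], key, mul / sz)
                    if log_sz > 0.0:
                        bump(tables["WAA"], key, add / log_sz)
                        bump(tables["rWAA"], key, mul / log_sz)
    if n_zero_strength:
        logger.info("%d hub node(s) with zero strength contributed no WRA/WAA terms", n_zero_strength)

    # length-3 simple-path accumulator: x - m - n - y over each edge (m, n)
    lp: PairTable = {}
    alpha = config.alpha_path
    if alpha > 0.0:
        for m, n, d in net.edges(data=True):
            wmn = d.get("weight", 1.0)
            if wmn == 0.0:
                continue
            for x in net[m]:
                if x == n:
                    continue
                wxm = w[_pair_key(x, m)]
                if wxm == 0.0:
                    continue
                for y in net[n]:
                    if y == m or y == x:
                        continue
                    # both orientations of the edge act as the middle leg
                    bump(lp, _pair_key(x, y), wxm * wmn * w[_pair_key(n, y)])
    for base, name in (("rWCN", "rWCNLP"), ("rWRA", "rWRALP"), ("rWAA", "rWAALP")):
        t = dict(tables[base])
        for key, val in lp.items():
            if config.lp_only_unconnected and net.has_edge(*key):
                continue
            t[key] = t.get(key, 0.0) + alpha * val
        tables[name] = t
    return tables


def topo_index(net: nx.Graph, index: str, config: RganConfig | None = None) -> PairTable:
    """One of the nine weighted topological similarity score tables.

    Returns a sparse mapping ``(gene_a, gene_b) -> score`` over unordered
    pairs with a nonzero score; absent pairs score 0.
    """
    config = config or RganConfig()
    if index not in INDEX_NAMES:
        raise ValueError(f"unknown index {index!r}; expected one of {INDEX_NAMES}")
    return _compute_index_tables(net, config)[index]


def _normalize_table(table: PairTable, mode: str) -> PairTable:
    if not table:
        return {}
    if mode == "none":
        return dict(table)
    if mode == "max":
        m = max(table.values())
        if m <= 0:
            return {}
        return {k: v / m for k, v in table.items()}
    # rank: normalised average ranks of the positive scores, in (0, 1]
    items = sorted(table.items(), key=lambda kv: (kv[1], kv[0]))
    n = len(items)
    ranks: dict[tuple[str, str], float] = {}
    i = 0
    while i < n:
        j = i
        while j + 1 < n and items[j + 1][1] == items[i][1]:
            j += 1
        avg = (i + j + 2) / 2.0  # 1-based average rank of the tie block
        for k in range(i, j + 1):
            ranks[items[k][0]] = avg / n
        i = j + 1
    return ranks


def build_rgan(net: nx.Graph, config: RganConfig | None = None) -> SimilarityMatrix:
    """Combine the nine (normalized) index tables into the RGAN matrix.

    Gene order follows the sorted node set of ``net``; pairs scored by no
    index are 0.  With ``normalize="max"`` every entry lies in [0, 1].
    """
    config = config or RganConfig()
    tables = _compute_index_tables(net, config)
    genes = sorted(net.nodes)
    idx = {g: i for i, g in enumerate(genes)}
    vals = np.zeros((len(genes), len(genes)))
    for name, weight in zip(INDEX_NAMES, config.index_weights):
        table = tables[name]
        if not table:
            logger.warning("index %s produced an all-zero table; it contributes 0", name)
            continue
        for (a, b), score in _normalize_table(table, config.normalize).items():
            i, j = idx[a], idx[b]
            vals[i, j] += weight * score
            vals[j, i] = vals[i, j]
    validate = config.normalize != "none"
    return SimilarityMatrix(genes, vals, validate=validate)
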