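"""Integration of per-ontology and per-method gene functional similarities.

Gene functional similarity can be scored under each of the three GO
aspects (cellular component, molecular function, biological process) and
by several semantic-similarity methods.  Both integration steps use the
same complement-geometric-mean combinator

    merged = 1 - (prod_n (1 - s_n))**(1/N)

which treats each source as independent evidence: a single source at 1
forces the merged value to 1, while a source at 0 contributes a neutral
factor.  Applied over all gene pairs this yields the integrated gene
functional similarity network (IGFSN), a fully connected [0, 1]
similarity matrix.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core import OntologyTriple, SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "complement_geometric_merge",
    "merge_ontologies",
    "merge_methods",
    "build_igfsn",
    "similarity_vs_distance",
]

#: floor applied to (1 - s) before taking logs, guards underflow as s -> 1
_LOG_FLOOR = 1e-300


def complement_geometric_merge(
    stack: np.ndarray,
    *,
    missing_mask: np.ndarray | None = None,
    renormalize_exponent: bool = False,
) -> np.ndarray:
    """Entrywise ``1 - (prod_k (1 - s_k))**(1/K)`` over axis 0.

    ``missing_mask`` (same shape as ``stack``, True = value absent) controls
    the convention for unannotated pairs: by default a missing source is
    treated as similarity 0 (a neutral factor of 1, fixed exponent K); with
    ``renormalize_exponent`` the exponent counts only present sources, and
    entries with no present source at all merge to 0.
    """
    stack = np.asarray(stack, dtype=float)
    comp = 1.0 - stack
    if missing_mask is not None:
        comp = np.where(missing_mask, 1.0, comp)
    logs = np.log(np.maximum(comp, _LOG_FLOOR))
    if renormalize_exponent and missing_mask is not None:
        k = np.sum(~missing_mask, axis=0)
        total = np.sum(np.where(missing_mask, 0.0, logs), axis=0)
        with np.errstate(invalid="ignore"):
            mean_log = np.where(k > 0, total / np.maximum(k, 1), 0.0)
    else:
        mean_log = logs.mean(axis=0)
    out = 1.0 - np.exp(mean_log)
    # exact absorption: any present source at 1 forces the merge to 1
    present = np.ones(stack.shape, dtype=bool) if missing_mask is None else ~missing_mask
    out[np.any((stack >= 1.0) & present, axis=0)] = 1.0
    return np.clip(out, 0.0, 1.0)


def _merge_matrices(
    mats: Sequence[SimilarityMatrix], renormalize_exponent: bool
) -> SimilarityMatrix:
    if not mats:
        raise ValueError("need at least one similarity matrix")
    genes = mats[0].genes
    for m in mats[1:]:
        if m.genes != genes:
            raise ValueError("similarity matrices have misaligned gene lists")
    stack = np.stack([m.values for m in mats])
    merged = complement_geometric_merge(stack, renormalize_exponent=renormalize_exponent)
    return SimilarityMatrix(genes, merged, validate=False)


def merge_ontologies(triple: OntologyTriple, *, renormalize_exponent: bool = False) -> SimilarityMatrix:
    """Merge one method's CC/MF/BP matrices (complement geometric mean, K=3)."""
    return _merge_matrices(triple.matrices(), renormalize_exponent)


def merge_methods(
    merged: Sequence[SimilarityMatrix], *, renormalize_exponent: bool = False
) -> SimilarityMatrix:
    """Merge per-method matrices into the IGFSN (exponent 1/N over N methods)."""
    return _merge_matrices(list(merged), renormalize_exponent)


def build_igfsn(
    triples: Sequence[OntologyTriple], *, renormalize_exponent: bool = False
) -> SimilarityMatrix:
    """Convenience: per-method ontology merge followed by the method merge."""
    per_method = [merge_ontologies(t, renormalize_exponent=renormalize_exponent) for t in triples]
    return merge_methods(per_method, renormalize_exponent=renormalize_exponent)


def similarity_vs_distance(
    sim: SimilarityMatrix,
    net: nx.Graph,
    *,
    max_distance: int = 5,
    pairs_per_distance: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Stratify similarity values by shortest-path distance in a PPI network.

    For each distance ``d`` in 1..max_distance, up to ``pairs_per_distance``
    unordered gene pairs at exactly distance ``d`` are sampled uniformly
    (seeded) and their similarity values summarised.  Returns a frame with
    columns ``distance``, ``n_pairs``, ``median`` and ``values``; empty
    strata carry ``n_pairs == 0`` and a NaN median (with a warning).
    """
    if pairs_per_distance < 1:
        raise ValueError("pairs_per_distance must be >= 1")
    shared = [g for g in sim.genes if g in net]
    if not shared:
        raise ValueError("similarity matrix and network share no genes")
    rng = np.random.default_rng(seed)
    strata: dict[int, list[tuple[str, str]]] = {d: [] for d in range(1, max_distance + 1)}
    for src, lengths in nx.all_pairs_shortest_path_length(net.subgraph(shared), cutoff=max_distance):
        for dst, d in lengths.items():
            if 1 <= d <= max_distance and src < dst:
                strata[d].append((src, dst))
    records = []
    for d in range(1, max_distance + 1):
        pairs = sorted(strata[d])
        if not pairs:
            logger.warning("no gene pairs at shortest-path distance %d", d)
            records.append({"distance": d, "n_pairs": 0, "median": float("nan"), "values": []})
            continue
        if len(pairs) > pairs_per_distance:
            idx = rng.choice(len(pairs), size=pairs_per_distance, replace=False)
            pairs = [pairs[i] for i in sorted(idx)]
        vals = [sim.get(a, b) for a, b in pairs]
        records.append(
            {"distance": d, "n_pairs": len(vals), "median": float(np.median(vals)), "values": vals}
        )
    return pd.DataFrame.from_records(records)
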