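"""Pruning the IGFSN against the RGAN and repairing connectivity.

A gene pair keeps its integrated functional similarity only when the
reference network agrees with it:

    sim_RGFSN(A,B) = sim_IGFSN(A,B)   if |sim_IGFSN - sim_RGAN| < tol
                                         and sim_RGAN != 0
                   = 0                otherwise

Kept values are bit-identical to the IGFSN values.  Pruning can strand
genes or small components outside the giant component; the repair step
reconnects each of them through its single best (highest-IGFSN) edge
into the giant component so the refined network is one connected graph.
"""

from __future__ import annotations

import dataclasses
import logging

import networkx as nx
import numpy as np

from .core import SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = ["RefineConfig", "RefineReport", "refine", "repair_connectivity"]


@dataclasses.dataclass
class RefineConfig:
    tolerance: float = 0.1
    reconnect: bool = True

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


@dataclasses.dataclass
class RefineReport:
    kept_edges: int = 0
    removed_edges: int = 0
    components_before_repair: int = 0
    isolated_genes: int = 0
    edges_added_by_repair: int = 0
    unrepairable_genes: int = 0

    def to_dict(self) -> dict[str, int]:
        return dataclasses.asdict(self)


def refine(
    igfsn: SimilarityMatrix, rgan: SimilarityMatrix, config: RefineConfig | None = None
) -> tuple[SimilarityMatrix, RefineReport]:
    """Apply the agreement filter entrywise; returns (RGFSN, report).

    Candidate pairs are the positive off-diagonal IGFSN entries; each is
    either kept (value unchanged) or removed (set to 0).
    """
    config = config or RefineConfig()
    if igfsn.genes != rgan.genes:
        raise ValueError("IGFSN and RGAN gene lists are misaligned")
    a, r = igfsn.values, rgan.values
    keep = (np.abs(a - r) < config.tolerance) & (r != 0.0)
    out = np.where(keep, a, 0.0)
    np.fill_diagonal(out, 1.0)
    iu = np.triu_indices(len(igfsn.genes), k=1)
    candidates = a[iu] > 0.0
    kept = int(np.sum(keep[iu] & candidates))
    report = RefineReport(kept_edges=kept, removed_edges=int(np.sum(candidates)) - kept)
    rgfsn = SimilarityMatrix(igfsn.genes, out, validate=False)
    if config.reconnect:
        rgfsn, report = repair_connectivity(rgfsn, igfsn, report=report)
    else:
        graph = rgfsn.to_graph()
        report.components_before_repair = nx.number_connected_components(graph)
        report.isolated_genes = sum(1 for n in graph if graph.degree(n) == 0)
    return rgfsn, report


def repair_connectivity(
    rgfsn: SimilarityMatrix,
    igfsn: SimilarityMatrix,
    *,
    report: RefineReport | None = None,
) -> tuple[SimilarityMatrix, RefineReport]:
    """Reconnect stranded genes/components to the giant component.

    Each connected component outside the largest one is attached through
    exactly one IGFSN edge: the (component node, giant node) pair with
    the highest IGFSN similarity, ties broken lexicographically by the
    gene-id pair.  Added edges carry their IGFSN values.  A component
    with no positive IGFSN similarity toward the giant component is left
    stranded with a warning.
    """
    if rgfsn.genes != igfsn.genes:
        raise ValueError("RGFSN and IGFSN gene lists are misaligned")
    report = report or RefineReport()
    graph = rgfsn.to_graph()
    comps = sorted(nx.connected_components(graph), key=lambda c: (-len(c), min(c)))
    report.components_before_repair = len(comps)
    report.isolated_genes = sum(1 for c in comps if len(c) == 1)
    if len(comps) <= 1:
        return rgfsn, report
    giant = comps[0]
    out = rgfsn.values.copy()
    giant_idx = np.array(sorted(igfsn.index_of(g) for g in giant))
    giant_genes = [igfsn.genes[i] for i in giant_idx]
    for comp in comps[1:]:
        comp_genes = sorted(comp)
        comp_idx = np.array([igfsn.index_of(g) for g in comp_genes])
        block = igfsn.values[np.ix_(comp_idx, giant_idx)]
        best = block.max()
        if best <= 0.0:
            report.unrepairable_genes += len(comp)
            logger.warning(
                "component %r has no positive similarity to the giant component; left stranded",
                comp_genes[:5],
            )
            continue
        ci, gi = np.unravel_index(np.argmax(_tie_broken(block, comp_genes, giant_genes)), block.shape)
        i, j = comp_idx[ci], giant_idx[gi]
        out[i, j] = out[j, i] = igfsn.values[i, j]
        report.edges_added_by_repair += 1
    repaired = SimilarityMatrix(rgfsn.genes, out, validate=False)
    return repaired, report


def _tie_broken(block: np.ndarray, comp_genes: list[str], giant_genes: list[str]) -> np.ndarray:
    """Perturb a score block so argmax prefers lexicographically smaller pairs.

    Scores differing by less than 1e-15 are treated as tied; within a tie
    the pair (comp_gene, giant_gene) smallest under tuple ordering wins.
    Rows/columns arrive sorted, so subtracting a tiny, strictly increasing
    offset in row-major order realises that preference.
    """
    n, m = block.shape
    offsets = np.arange(n * m, dtype=float).reshape(n, m)
    return block - 1e-15 * offsets
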