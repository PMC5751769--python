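"""Synthetic data generators: every pipeline stage is testable offline.

The generators emulate the shapes of the real inputs — sparse scale-free
PPI graphs, per-method/per-ontology similarity matrices whose values
decay with PPI shortest-path distance, and planted complex catalogues
with controllable overlap between "reference" and "predicted" sets.
They make no attempt to simulate realistic GO DAG topology or
annotation corpora; a toy DAG with an information-content helper is
provided only so term-level plumbing can be exercised.

Each generator draws from its own named pseudo-random stream derived
from the single spec seed, so adding a generator never perturbs
existing fixtures and every output is bit-reproducible from the spec.
"""

from __future__ import annotations

import dataclasses
import math

import networkx as nx
import numpy as np

from .core import ComplexSet, OntologyTriple, SimilarityMatrix

__all__ = [
    "FixtureSpec",
    "make_ppi",
    "make_method_matrices",
    "make_planted_complexes",
    "toy_go_dag",
    "information_content",
]

# per-generator stream tags, appended to the spec seed in a SeedSequence
_STREAMS = {"ppi": 1, "sim": 2, "complexes": 3}

_ONTOLOGIES = ("cc", "mf", "bp")


@dataclasses.dataclass
class FixtureSpec:
    """Study conditions for one synthetic dataset.

    n_genes
        Number of genes (>= 3).
    seed
        Single integer seed; fully determines every generator's output.
    graph_model
        ``preferential_attachment`` (heavy-tailed degrees, the
        biological default), ``erdos_renyi`` or ``small_world``.
    sim_agreement
        Correlation knob in [0, 1] between the generated "method"
        matrices: 1 makes all methods share one noise realisation,
        0 makes their noise independent.
    noise_sd
        Standard deviation of the additive similarity noise.
    edges_per_node / edge_prob / rewire_prob
        Model-specific density knobs.
    """

    n_genes: int = 200
    seed: int = 0
    graph_model: str = "preferential_attachment"
    sim_agreement: float = 0.8
    noise_sd: float = 0.05
    edges_per_node: int = 3
    edge_prob: float = 0.05
    rewire_prob: float = 0.1

    def __post_init__(self) -> None:
        if self.n_genes < 3:
            raise ValueError("n_genes must be >= 3")
        if not 0.0 <= self.sim_agreement <= 1.0:
            raise ValueError("sim_agreement must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"g{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, _STREAMS[stream])))


def make_ppi(spec: FixtureSpec) -> nx.Graph:
    """A seeded simple undirected PPI-like graph with gene-id labels."""
    rng = spec.rng("ppi")
    nx_seed = int(rng.integers(0, 2**31 - 1))
    n = spec.n_genes
    if spec.graph_model == "preferential_attachment":
        m = min(spec.edges_per_node, n - 1)
        # an (m+1)-clique seed gives every node degree >= m, avoiding the
        # spurious sub-m degree bins a star-seeded growth process leaves
        g = nx.barabasi_albert_graph(n, m, seed=nx_seed, initial_graph=nx.complete_graph(m + 1))
    elif spec.graph_model == "erdos_renyi":
        g = nx.fast_gnp_random_graph(n, spec.edge_prob, seed=nx_seed)
        if spec.edge_prob >= 1.0:
            g = nx.complete_graph(n)
    elif spec.graph_model == "small_world":
        k = max(2, 2 * (spec.edges_per_node // 2) or 2)
        g = nx.watts_strogatz_graph(n, min(k, n - 1), spec.rewire_prob, seed=nx_seed)
    else:
        raise ValueError(f"unknown graph model {spec.graph_model!r}")
    genes = spec.gene_ids()
    g = nx.relabel_nodes(g, dict(enumerate(genes)))
    g.add_nodes_from(genes)
    nx.set_edge_attributes(g, 1.0, "weight")
    return g


def distance_decay(distance: float) -> float:
    """Baseline similarity for a gene pair at a given PPI distance."""
    return 0.9 * math.exp(-0.3 * (distance - 1.0))


#: baseline similarity assigned to pairs with no connecting path
_UNREACHABLE_BASE = 0.02


def make_method_matrices(
    spec: FixtureSpec, ppi: nx.Graph, n_methods: int = 6
) -> list[OntologyTriple]:
    """Per-method CC/MF/BP similarity matrices tied to PPI proximity.

    Every matrix is ``clamp(base(distance) + noise)`` with the baseline
    strictly decreasing in shortest-path distance.  The noise of method
    m under ontology o is ``noise_sd * (sqrt(a) * C_o + sqrt(1-a) *
    E_{m,o})`` with a shared component C_o and independent components
    E_{m,o}, so ``sim_agreement`` a controls inter-method correlation
    (a = 1, or noise_sd = 0, makes all methods identical).
    """
    if n_methods < 1:
        raise ValueError("n_methods must be >= 1")
    genes = sorted(ppi.nodes)
    n = len(genes)
    idx = {g: i for i, g in enumerate(genes)}
    base = np.full((n, n), _UNREACHABLE_BASE)
    for src, lengths in nx.all_pairs_shortest_path_length(ppi):
        i = idx[src]
        for dst, d in lengths.items():
            if d >= 1:
                base[i, idx[dst]] = distance_decay(d)
    rng = spec.rng("sim")
    iu = np.triu_indices(n, k=1)

    def sym_noise() -> np.ndarray:
        out = np.zeros((n, n))
        out[iu] = rng.standard_normal(len(iu[0]))
        return out + out.T

    shared = {o: sym_noise() for o in _ONTOLOGIES}
    a = spec.sim_agreement
    triples = []
    for _ in range(n_methods):
        mats = {}
        for o in _ONTOLOGIES:
            noise = math.sqrt(a) * shared[o] + math.sqrt(1.0 - a) * sym_noise()
            vals = np.clip(base + spec.noise_sd * noise, 0.0, 1.0)
            np.fill_diagonal(vals, 1.0)
            mats[o] = SimilarityMatrix(genes, vals, validate=False)
        triples.append(OntologyTriple(**mats))
    return triples


def make_planted_complexes(
    spec: FixtureSpec,
    n_complexes: int = 20,
    overlap: float = 0.8,
    complex_size: int = 10,
) -> tuple[ComplexSet, ComplexSet]:
    """(reference, predicted) complex catalogues with planted overlap.

    Reference complexes are disjoint random gene sets; each prediction
    copies its reference and swaps a (1 - overlap) fraction of members
    for fresh genes from a disjoint replacement universe.  ``overlap=1``
    gives identical catalogues, ``overlap=0`` fully disjoint ones.
    """
    if not 0.0 <= overlap <= 1.0:
        raise ValueError("overlap must lie in [0, 1]")
    if n_complexes * complex_size > spec.n_genes:
        raise ValueError(
            f"{n_complexes} disjoint complexes of size {complex_size} need "
            f">= {n_complexes * complex_size} genes, spec has {spec.n_genes}"
        )
    rng = spec.rng("complexes")
    genes = spec.gene_ids()
    perm = rng.permutation(len(genes))
    reference, predicted = {}, {}
    n_swap = complex_size - round(overlap * complex_size)
    fresh = 0
    for c in range(n_complexes):
        members = [genes[perm[c * complex_size + k]] for k in range(complex_size)]
        reference[f"ref_{c + 1}"] = list(members)
        pred = list(members)
        swap_at = rng.choice(complex_size, size=n_swap, replace=False)
        for pos in swap_at:
            fresh += 1
            pred[pos] = f"x{fresh:05d}"  # replacement universe disjoint from gene ids
        predicted[f"pred_{c + 1}"] = pred
    return ComplexSet(reference), ComplexSet(predicted)


# ---------------------------------------------------------------------------
# toy ontology helpers (plumbing-scale only)

def toy_go_dag() -> nx.DiGraph:
    """A tiny is-a DAG (edges child -> parent) for exercising term plumbing."""
    dag = nx.DiGraph()
    edges = [
        ("t_leaf_a", "t_mid_1"), ("t_leaf_b", "t_mid_1"),
        ("t_leaf_c", "t_mid_2"), ("t_mid_1", "t_root"),
        ("t_mid_2", "t_root"), ("t_leaf_b", "t_mid_2"),
    ]
    dag.add_edges_from(edges)
    return dag


def information_content(dag: nx.DiGraph, annotations: dict[str, set[str]]) -> dict[str, float]:
    """IC(t) = -ln p(t) with annotation counts propagated to ancestors.

    ``annotations`` maps gene -> directly annotated terms; a term's count
    includes genes annotated to any of its descendants.  Terms with zero
    count get no IC entry; the root always has IC 0.
    """
    counts: dict[str, int] = {t: 0 for t in dag}
    for terms in annotations.values():
        covered: set[str] = set()
        for t in terms:
            if t in dag:
                covered.add(t)
                covered.update(nx.descendants(dag, t))  # ancestors under child->parent edges
        for t in covered:
            counts[t] += 1
    total = len(annotations)
    return {
        t: -math.log(c / total) for t, c in counts.items() if c > 0 and total > 0
    }
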