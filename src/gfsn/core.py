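"""Core in-memory containers shared across the pipeline.

Gene identifiers are opaque strings (symbols or database accessions);
comparison is exact string equality after whitespace trimming and case is
preserved.  Networks are plain :class:`networkx.Graph` objects whose nodes
are gene identifiers and whose edges carry a non-negative ``weight``
attribute.  Similarity matrices are dense, symmetric, [0, 1]-valued arrays
with unit diagonal over an explicit gene ordering.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping

import networkx as nx
import numpy as np

__all__ = [
    "SimilarityMatrix",
    "OntologyTriple",
    "ComplexSet",
    "clean_gene_id",
]

#: tolerance used when validating symmetry and the [0, 1] range
_EPS = 1e-9


def clean_gene_id(token: str) -> str:
    """Normalise a raw gene token: trim whitespace, preserve case."""
    g = str(token).strip()
    if not g:
        raise ValueError("empty gene identifier")
    return g


class SimilarityMatrix:
    """A symmetric gene-by-gene similarity matrix with values in [0, 1].

    Parameters
    ----------
    genes
        Ordered gene identifiers; must contain no duplicates.
    values
        Square array aligned with ``genes``.  Symmetry is enforced to
        1e-9 on input (stored symmetrised to machine precision); values
        within 1e-9 outside [0, 1] are clamped, anything further out is
        an error.  The diagonal is forced to 1.
    """

    def __init__(self, genes: Iterable[str], values: np.ndarray, *, validate: bool = True):
        self.genes: list[str] = [clean_gene_id(g) for g in genes]
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers in similarity matrix")
        values = np.asarray(values, dtype=float)
        n = len(self.genes)
        if values.shape != (n, n):
            raise ValueError(f"matrix shape {values.shape} does not match {n} genes")
        if validate:
            asym = np.abs(values - values.T)
            if asym.size and np.nanmax(asym) > _EPS:
                i, j = np.unravel_index(np.argmax(asym), asym.shape)
                raise ValueError(
                    f"asymmetric similarity input: m[{self.genes[i]},{self.genes[j]}]"
                    f"={values[i, j]!r} vs transposed {values[j, i]!r}"
                )
            if values.size and (np.nanmin(values) < -_EPS or np.nanmax(values) > 1 + _EPS):
                bad = values[(values < -_EPS) | (values > 1 + _EPS)]
                raise ValueError(f"similarity values outside [0,1]: e.g. {bad.flat[0]!r}")
            values = np.clip(values, 0.0, 1.0)
            values = (values + values.T) / 2.0
        np.fill_diagonal(values, 1.0)
        self.values: np.ndarray = values
        self._index: dict[str, int] = {g: i for i, g in enumerate(self.genes)}

    # -- access -----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.genes)

    def index_of(self, gene: str) -> int:
        return self._index[gene]

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def aligned_with(self, other: "SimilarityMatrix") -> bool:
        return self.genes == other.genes

    def copy(self) -> "SimilarityMatrix":
        return SimilarityMatrix(self.genes, self.values.copy(), validate=False)

    # -- conversions ------------------------------------------------------
    def to_graph(self) -> nx.Graph:
        """Positive off-diagonal entries as an undirected weighted graph.

        Every gene appears as a node even when it has no positive entry,
        so connectivity analyses see isolated genes.
        """
        g = nx.Graph()
        g.add_nodes_from(self.genes)
        iu, ju = np.triu_indices(len(self.genes), k=1)
        vals = self.values[iu, ju]
        nz = vals > 0
        g.add_weighted_edges_from(
            (self.genes[i], self.genes[j], float(v))
            for i, j, v in zip(iu[nz], ju[nz], vals[nz])
        )
        return g

    @classmethod
    def from_graph(cls, graph: nx.Graph, genes: Iterable[str] | None = None) -> "SimilarityMatrix":
        genes = list(genes) if genes is not None else sorted(graph.nodes)
        idx = {g: i for i, g in enumerate(genes)}
        vals = np.zeros((len(genes), len(genes)))
        for u, v, w in graph.edges(data="weight", default=1.0):
            if u in idx and v in idx:
                vals[idx[u], idx[v]] = vals[idx[v], idx[u]] = w
        return cls(genes, vals)

    def __repr__(self) -> str:
        return f"SimilarityMatrix({len(self.genes)} genes)"


@dataclasses.dataclass
class OntologyTriple:
    """Per-ontology similarity matrices for one method (CC, MF, BP)."""

    cc: SimilarityMatrix
    mf: SimilarityMatrix
    bp: SimilarityMatrix

    def __post_init__(self) -> None:
        if not (self.cc.aligned_with(self.mf) and self.cc.aligned_with(self.bp)):
            raise ValueError("CC/MF/BP matrices must share an identical gene list")

    @property
    def genes(self) -> list[str]:
        return self.cc.genes

    def matrices(self) -> list[SimilarityMatrix]:
        return [self.cc, self.mf, self.bp]


class ComplexSet:
    """A named collection of gene sets (protein complexes), each of size >= 2."""

    def __init__(self, complexes: Mapping[str, Iterable[str]], *, min_size: int = 2):
        self.complexes: dict[str, frozenset[str]] = {}
        self.n_dropped: int = 0
        for name, members in complexes.items():
            mem = frozenset(clean_gene_id(m) for m in members)
            if len(mem) < min_size:
                self.n_dropped += 1
                continue
            if name in self.complexes:
                raise ValueError(f"duplicate complex name {name!r}")
            self.complexes[str(name)] = mem

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self):
        return iter(self.complexes.items())

    def names(self) -> list[str]:
        return list(self.complexes)

    def members(self) -> set[str]:
        out: set[str] = set()
        for mem in self.complexes.values():
            out |= mem
        return out

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ComplexSet) and self.complexes == other.complexes

    def __repr__(self) -> str:
        return f"ComplexSet({len(self)} complexes)"
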