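"""Readers and writers for edge lists, similarity matrices and complex catalogues.

Formats
-------
* Edge lists: TSV/CSV with 2-3 columns (``source target [weight]``); lines
  starting with ``#`` are comments.  SIF (``node relation node ...``) is
  accepted when the middle column is non-numeric.
* Similarity matrices: dense TSV with a header row and a leading label
  column, or long-format triples ``gene<TAB>gene<TAB>value``.
* Complexes: TSV (``name<TAB>member;member;...``) or XLSX spreadsheets.

All writers are deterministic: nodes and edges are emitted in
lexicographic order, floats with 17 significant digits so a write/read
round trip is exact.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .core import ComplexSet, SimilarityMatrix, clean_gene_id

logger = logging.getLogger(__name__)

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "read_complexes",
    "write_complexes",
    "restrict_to_genes",
    "largest_connected_component",
    "apply_gene_mapping",
    "read_gene_list",
]

_FLOAT = "%.17g"


def _split_line(line: str) -> list[str]:
    if "\t" in line:
        return [t for t in line.split("\t") if t.strip()]
    if "," in line:
        return [t for t in line.split(",") if t.strip()]
    return line.split()


def read_edge_list(path: str | Path, has_weights: bool = False) -> nx.Graph:
    """Read an undirected simple graph from a TSV/CSV/SIF edge list.

    Duplicate edges are collapsed keeping the maximum weight; self-loops
    are dropped.  Both drop counts are logged.
    """
    path = Path(path)
    graph = nx.Graph()
    n_self, n_dup = 0, 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            toks = _split_line(line)
            if len(toks) < 2:
                raise ValueError(f"{path}:{lineno}: need at least two columns")
            if len(toks) >= 3 and not has_weights and not _is_number(toks[1]) and not _is_number(toks[2]):
                # SIF: node relation node [node ...]
                src, partners = toks[0], toks[2:]
                pairs = [(src, t) for t in partners]
                weight = 1.0
            else:
                pairs = [(toks[0], toks[1])]
                weight = 1.0
                if has_weights:
                    if len(toks) < 3:
                        raise ValueError(f"{path}:{lineno}: weight column missing")
                    try:
                        weight = float(toks[2])
                    except ValueError:
                        raise ValueError(
                            f"{path}:{lineno}: non-numeric weight {toks[2]!r}"
                        ) from None
                    if weight < 0:
                        raise ValueError(f"{path}:{lineno}: negative weight {weight}")
            for a, b in pairs:
                a, b = clean_gene_id(a), clean_gene_id(b)
                if a == b:
                    n_self += 1
                    continue
                if graph.has_edge(a, b):
                    n_dup += 1
                    if weight > graph[a][b]["weight"]:
                        graph[a][b]["weight"] = weight
                else:
                    graph.add_edge(a, b, weight=weight)
    if n_self or n_dup:
        logger.info(
            "%s: dropped %d self-loop(s), collapsed %d duplicate edge(s)",
            path.name, n_self, n_dup,
        )
    graph.graph["n_self_loops_dropped"] = n_self
    graph.graph["n_duplicates_collapsed"] = n_dup
    return graph


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def write_edge_list(graph: nx.Graph, path: str | Path, *, weights: bool = True) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
            if weights:
                w = graph[u][v].get("weight", 1.0)
                fh.write(f"{u}\t{v}\t{_FLOAT % w}\n")
            else:
                fh.write(f"{u}\t{v}\n")
        # isolated nodes are preserved as commented records
        for n in sorted(graph.nodes):
            if graph.degree(n) == 0:
                fh.write(f"#node\t{n}\n")


def _read_isolated_nodes(path: Path) -> list[str]:
    out = []
    with path.open() as fh:
        for line in fh:
            if line.startswith("#node\t"):
                out.append(line.split("\t", 1)[1].strip())
    return out


def read_network(path: str | Path) -> nx.Graph:
    """Read a weighted edge list written by :func:`write_edge_list`."""
    g = read_edge_list(path, has_weights=True)
    g.add_nodes_from(_read_isolated_nodes(Path(path)))
    return g


def read_similarity_matrix(path: str | Path) -> SimilarityMatrix:
    """Read a similarity matrix from dense-TSV or long-format triples.

    Dense input must be square with matching row/column labels.  Values
    within 1e-9 outside [0, 1] are clamped; larger excursions and
    asymmetries beyond 1e-9 are errors.  The diagonal is forced to 1.
    """
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
    toks = first.rstrip("\n").split("\t")
    long_format = len(toks) == 3 and _is_number(toks[2]) and not _is_number(toks[1])
    if long_format:
        genes: dict[str, int] = {}
        triples: list[tuple[str, str, float]] = []
        with path.open() as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                t = line.split("\t") if "\t" in line else line.split()
                if len(t) != 3:
                    raise ValueError(f"{path}:{lineno}: expected 3 columns")
                a, b = clean_gene_id(t[0]), clean_gene_id(t[1])
                v = float(t[2])
                for g in (a, b):
                    genes.setdefault(g, len(genes))
                triples.append((a, b, v))
        order = list(genes)
        vals = np.zeros((len(order), len(order)))
        seen: dict[tuple[int, int], float] = {}
        for a, b, v in triples:
            i, j = genes[a], genes[b]
            key = (min(i, j), max(i, j))
            if key in seen and abs(seen[key] - v) > 1e-9 and i != j:
                raise ValueError(
                    f"{path}: asymmetric entries for pair ({a},{b}): {seen[key]} vs {v}"
                )
            seen[key] = v
            vals[i, j] = vals[j, i] = v
        return SimilarityMatrix(order, vals)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    rows = [clean_gene_id(str(r)) for r in df.index]
    cols = [clean_gene_id(str(c)) for c in df.columns]
    if rows != cols:
        raise ValueError(f"{path}: row labels do not match column labels (non-square)")
    return SimilarityMatrix(rows, df.to_numpy(dtype=float))


def write_similarity_matrix(sim: SimilarityMatrix, path: str | Path, *, fmt: str = "dense") -> None:
    path = Path(path)
    if fmt == "dense":
        with path.open("w") as fh:
            fh.write("\t" + "\t".join(sim.genes) + "\n")
            for i, g in enumerate(sim.genes):
                row = "\t".join(_FLOAT % v for v in sim.values[i])
                fh.write(f"{g}\t{row}\n")
    elif fmt == "long":
        with path.open("w") as fh:
            order = np.argsort(sim.genes)
            genes = [sim.genes[i] for i in order]
            vals = sim.values[np.ix_(order, order)]
            for i, a in enumerate(genes):
                for j in range(i + 1, len(genes)):
                    v = vals[i, j]
                    if v > 0:
                        fh.write(f"{a}\t{genes[j]}\t{_FLOAT % v}\n")
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")


def read_complexes(path: str | Path, *, delimiters: str = ",;| ", min_size: int = 2) -> ComplexSet:
    """Read a complex catalogue from TSV or XLSX.

    Each row holds a complex name and a member list.  The first column
    whose cells split into >= 2 tokens under any configured delimiter is
    taken as the member column.  Complexes with fewer than ``min_size``
    distinct members are dropped (count logged).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".xls":
        raise ValueError(
            f"{path}: legacy binary .xls is not supported; convert to .xlsx or TSV"
        )
    if suffix == ".xlsx":
        df = pd.read_excel(path, engine="openpyxl")
        rows = [[("" if pd.isna(c) else str(c)) for c in rec] for rec in df.itertuples(index=False)]
    else:
        rows = []
        with path.open() as fh:
            reader = csv.reader(fh, delimiter="\t")
            for rec in reader:
                if not rec or (rec[0].startswith("#")):
                    continue
                rows.append([c.strip() for c in rec])
    if not rows:
        raise ValueError(f"{path}: no rows")
    member_col = _find_member_column(rows, delimiters)
    complexes: dict[str, list[str]] = {}
    for k, rec in enumerate(rows):
        if member_col >= len(rec) or not rec[member_col].strip():
            continue
        name = rec[0].strip() if member_col != 0 and rec[0].strip() else f"complex_{k + 1}"
        members = _split_members(rec[member_col], delimiters)
        base, suffix_i = name, 1
        while name in complexes:
            suffix_i += 1
            name = f"{base}_{suffix_i}"
        complexes[name] = members
    cs = ComplexSet(complexes, min_size=min_size)
    if cs.n_dropped:
        logger.info("%s: dropped %d complex(es) with <%d members", path.name, cs.n_dropped, min_size)
    if not len(cs):
        raise ValueError(f"{path}: no parsable complexes of size >= {min_size}")
    return cs


def _split_members(cell: str, delimiters: str) -> list[str]:
    for d in delimiters:
        if d in cell.strip():
            return [t.strip() for t in cell.split(d) if t.strip()]
    return [cell.strip()] if cell.strip() else []


def _find_member_column(rows: list[list[str]], delimiters: str) -> int:
    ncols = max(len(r) for r in rows)
    best, best_hits = None, 0
    for col in range(ncols):
        hits = sum(
            1 for r in rows if col < len(r) and len(_split_members(r[col], delimiters)) >= 2
        )
        if hits > best_hits:
            best, best_hits = col, hits
    if best is None:
        raise ValueError("no column parses as a member list under the configured delimiters")
    return best


def write_complexes(cs: ComplexSet, path: str | Path) -> None:
    """TSV writer: ``name<TAB>member;member;...`` sorted by name."""
    with Path(path).open("w") as fh:
        for name in sorted(cs.complexes):
            fh.write(f"{name}\t{';'.join(sorted(cs.complexes[name]))}\n")


def restrict_to_genes(network: nx.Graph, genes: set[str]) -> nx.Graph:
    """Induced subgraph on the intersection of the node set and ``genes``."""
    keep = set(network.nodes) & set(genes)
    if not keep:
        raise ValueError("empty intersection between network nodes and gene set")
    return network.subgraph(keep).copy()


def largest_connected_component(network: nx.Graph) -> nx.Graph:
    """The induced subgraph on the largest connected component.

    Ties on component size are broken by the lexicographically smallest
    member node, so the choice is deterministic.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    comps = sorted(nx.connected_components(network), key=lambda c: (-len(c), min(c)))
    return network.subgraph(comps[0]).copy()


def read_gene_list(path: str | Path) -> list[str]:
    out = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(clean_gene_id(line.split()[0]))
    return out


def apply_gene_mapping(network: nx.Graph, mapping_path: str | Path) -> nx.Graph:
    """Rename nodes via a two-column ``old<TAB>new`` mapping file."""
    mapping: dict[str, str] = {}
    with Path(mapping_path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            toks = _split_line(line)
            if len(toks) != 2:
                raise ValueError(f"{mapping_path}:{lineno}: expected two columns")
            mapping[clean_gene_id(toks[0])] = clean_gene_id(toks[1])
    return nx.relabel_nodes(network, mapping, copy=True)
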