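"""Per-pathway gene graphs and their symmetric-normalized adjacency operators.

Each pathway becomes an undirected, unweighted graph over its member
genes.  Graph convolution uses the renormalized operator

    S = D~^{-1/2} (A + I) D~^{-1/2},    D~_ii = sum_j (A + I)_ij,

which adds a self-loop to every node before degree normalization, so
isolated genes (degree 0 in the edge list) still carry their own signal.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .gene_sets import GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class PathwayGraph:
    """One pathway as an undirected 0/1 graph over its member genes.

    Attributes
    ----------
    pathway_id : str
    nodes : list of str
        Member genes in gene-set order; node identity is
        ``(pathway_id, gene)``, never global.
    adjacency : ndarray of shape (N, N)
        Symmetric binary, zero diagonal.
    norm_adjacency : ndarray of shape (N, N)
        ``D~^{-1/2} (A + I) D~^{-1/2}``; symmetric, non-negative,
        strictly positive diagonal.
    """

    pathway_id: str
    nodes: list[str]
    adjacency: np.ndarray
    norm_adjacency: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass
class GraphStats:
    pathway_id: str
    n_nodes: int
    n_edges: int
    edge_density: float


def normalized_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Return ``D~^{-1/2} (A + I) D~^{-1/2}`` for a binary symmetric A."""
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    a_tilde = a + np.eye(a.shape[0])
    deg = a_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(deg)
    return a_tilde * inv_sqrt[:, None] * inv_sqrt[None, :]


def build_graph(pathway_id: str, genes: list[str], edges: list[tuple[str, str]]) -> PathwayGraph:
    """Assemble a :class:`PathwayGraph` from member genes and undirected edges.

    Every edge endpoint must be a member gene.  Duplicate and reversed
    edges collapse to a single undirected edge; self-edges are ignored
    (the self-loop is added by the normalization, not the data).
    """
    index = {g: i for i, g in enumerate(genes)}
    if len(index) != len(genes):
        raise ValueError(f"{pathway_id}: duplicate genes in node list")
    n = len(genes)
    adj = np.zeros((n, n), dtype=np.int8)
    for a, b in edges:
        if a not in index or b not in index:
            raise ValueError(f"{pathway_id}: edge ({a},{b}) endpoint not in gene list")
        if a == b:
            continue
        i, j = index[a], index[b]
        adj[i, j] = 1
        adj[j, i] = 1
    return PathwayGraph(
        pathway_id=pathway_id,
        nodes=list(genes),
        adjacency=adj,
        norm_adjacency=normalized_adjacency(adj),
    )


def read_edge_list(path: str | Path, sets: GeneSetCollection) -> dict[str, list[tuple[str, str]]]:
    """Read a flat TSV edge list (``pathway  gene_a  gene_b``) per pathway.

    Edges are kept only when both genes belong to the named set; (a,b)
    and (b,a) collapse to one undirected edge; self-edges are dropped.
    Edges naming unknown pathways or non-member genes are dropped with a
    warning that reports the total count.  A pathway without edge rows
    simply yields an edgeless graph downstream.
    """
    path = Path(path)
    edges: dict[str, set[tuple[str, str]]] = {pid: set() for pid in sets.pathway_ids}
    members = {pid: set(genes) for pid, genes in sets.sets.items()}
    n_dropped = 0
    with path.open() as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            if row[0] == "pathway":  # header
                continue
            if len(row) < 3:
                n_dropped += 1
                continue
            pid, a, b = row[0], row[1], row[2]
            if pid not in members:
                n_dropped += 1
                continue
            if a == b:
                n_dropped += 1
                continue
            if a not in members[pid] or b not in members[pid]:
                n_dropped += 1
                continue
            edges[pid].add((a, b) if a <= b else (b, a))
    if n_dropped:
        logger.warning("read_edge_list: dropped %d invalid edge rows from %s", n_dropped, path)
    return {pid: sorted(e) for pid, e in edges.items()}


def write_edge_list(edges: dict[str, list[tuple[str, str]]], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("pathway\tgene_a\tgene_b\n")
        for pid, pairs in edges.items():
            for a, b in pairs:
                fh.write(f"{pid}\t{a}\t{b}\n")


def build_graphs(sets: GeneSetCollection, edges: dict[str, list[tuple[str, str]]]) -> list[PathwayGraph]:
    """Build one graph per set, in collection order."""
    return [
        build_graph(pid, sets[pid], edges.get(pid, []))
        for pid in sets.pathway_ids
    ]


def graph_stats(g: PathwayGraph) -> GraphStats:
    """Node/edge counts and edge density (realized edges over possible pairs)."""
    n = g.n_nodes
    e = g.n_edges
    density = 0.0 if n < 2 else e / (n * (n - 1) / 2)
    return GraphStats(pathway_id=g.pathway_id, n_nodes=n, n_edges=e, edge_density=density)
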