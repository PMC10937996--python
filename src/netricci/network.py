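"""Expression-weighted protein-interaction networks.

The central object is a :class:`MatchedNetwork`: an undirected, connected,
simple graph (the protein-interaction network, PIN) together with a strictly
positive expression vector aligned to its nodes.  Under the mass-action
principle an interacting protein pair (i, j) is weighted by the product of
the transcript abundances of its endpoints,

    W(x)_ij = a_ij * x_i * x_j,

which induces a random walk with row-stochastic transition matrix

    p_ij(x) = a_ij * x_j / sum_k a_ik x_k

and, because the graph is undirected and connected, a closed-form stationary
distribution proportional to the weighted node strength,

    pi_i(x) = x_i * sum_j a_ij x_j  (normalised to sum to 1).

All edge-valued quantities (weights, distances, curvatures) are carried by
:class:`EdgeField`, one value per undirected edge in a canonical (i < j)
ordering shared across a fixed topology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

__all__ = [
    "MatchedNetwork",
    "EdgeField",
    "PositivityError",
    "ValidationError",
    "load_network",
    "load_expression",
    "load_mapping",
    "match_expression",
    "weighted_adjacency",
    "transition_matrix",
    "stationary_distribution",
]


class ValidationError(ValueError):
    """Input fails a structural contract (empty graph, tiny component, ...)."""


class PositivityError(ValueError):
    """Matched expression values are not strictly positive."""


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EdgeField:
    """A real value per undirected edge of a fixed topology.

    ``edges`` is an (m, 2) integer array with ``edges[:, 0] < edges[:, 1]``,
    sorted lexicographically; ``values`` is aligned to it.  Symmetric access
    is provided by :meth:`value`.
    """

    edges: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=np.int64)
        values = np.asarray(self.values, dtype=float)
        if edges.ndim != 2 or edges.shape[1] != 2:
            raise ValidationError("edges must be an (m, 2) array")
        if values.shape != (edges.shape[0],):
            raise ValidationError("values must align with edges")
        if np.any(edges[:, 0] >= edges[:, 1]):
            raise ValidationError("edges must satisfy i < j")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "values", values)

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def value(self, i: int, j: int) -> float:
        a, b = (i, j) if i < j else (j, i)
        hit = np.flatnonzero((self.edges[:, 0] == a) & (self.edges[:, 1] == b))
        if hit.size == 0:
            raise KeyError(f"no edge ({i}, {j})")
        return float(self.values[hit[0]])

    def with_values(self, values: np.ndarray) -> "EdgeField":
        return EdgeField(self.edges, np.asarray(values, dtype=float))

    def same_edges(self, other: "EdgeField") -> bool:
        return self.edges.shape == other.edges.shape and bool(
            np.array_equal(self.edges, other.edges)
        )

    def to_matrix(self, n: int) -> sp.csr_matrix:
        """Dense-topology symmetric sparse matrix with this field's values."""
        i, j = self.edges[:, 0], self.edges[:, 1]
        m = sp.coo_matrix(
            (np.concatenate([self.values, self.values]),
             (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(n, n),
        )
        return m.tocsr()


def _canonical_edges(adjacency: sp.spmatrix) -> np.ndarray:
    coo = sp.triu(adjacency, k=1).tocoo()
    edges = np.stack([coo.row, coo.col], axis=1).astype(np.int64)
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    return edges[order]


@dataclass(frozen=True)
class MatchedNetwork:
    """A connected PIN with a strictly positive expression vector.

    Invariants enforced on construction: the adjacency is symmetric 0/1 with
    zero diagonal, the graph is a single connected component, node identifiers
    are unique, and every expression value is > 0.
    """

    node_ids: tuple
    adjacency: sp.csr_matrix
    expression: np.ndarray

    def __post_init__(self) -> None:
        ids = tuple(str(v) for v in self.node_ids)
        adj = sp.csr_matrix(self.adjacency, dtype=float)
        x = np.asarray(self.expression, dtype=float)
        n = len(ids)
        if len(set(ids)) != n:
            raise ValidationError("node identifiers must be unique")
        if adj.shape != (n, n):
            raise ValidationError("adjacency shape does not match node count")
        if x.shape != (n,):
            raise ValidationError("expression must align with nodes")
        if adj.diagonal().any():
            raise ValidationError("adjacency must have zero diagonal")
        if (adj != adj.T).nnz != 0:
            raise ValidationError("adjacency must be symmetric")
        data = adj.data
        if data.size and not np.all((data == 0) | (data == 1)):
            raise ValidationError("adjacency must be 0/1")
        n_comp, _ = connected_components(adj, directed=False)
        if n_comp != 1:
            raise ValidationError(f"graph has {n_comp} components; expected 1")
        if np.any(x <= 0) or not np.all(np.isfinite(x)):
            bad = [ids[i] for i in np.flatnonzero(~(x > 0))]
            raise PositivityError(
                f"expression must be strictly positive; offending nodes: {bad}"
            )
        object.__setattr__(self, "node_ids", ids)
        object.__setattr__(self, "adjacency", adj)
        object.__setattr__(self, "expression", x)

    @property
    def n(self) -> int:
        return len(self.node_ids)

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    @property
    def edge_index(self) -> np.ndarray:
        return _canonical_edges(self.adjacency)

    def edge_field(self, values: np.ndarray) -> EdgeField:
        return EdgeField(self.edge_index, values)

    def index_of(self, node_id: str) -> int:
        return self.node_ids.index(node_id)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_network(path, fmt: str | None = None) -> nx.Graph:
    """Read an undirected PIN from an edge list, GraphML or SIF file.

    Duplicate edges are collapsed; self-loops are dropped (with a logged
    count).  The format is inferred from the extension when ``fmt`` is None.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {".graphml": "graphml", ".sif": "sif"}.get(suffix, "edgelist")
    if fmt == "graphml":
        try:
            raw = nx.read_graphml(path)
        except Exception as exc:  # lxml/expat errors vary
            raise ValidationError(f"could not parse GraphML file {path}: {exc}") from exc
        graph = nx.Graph()
        graph.add_nodes_from(str(v) for v in raw.nodes)
        graph.add_edges_from((str(u), str(v)) for u, v in raw.edges)
    elif fmt == "sif":
        graph = nx.Graph()
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if len(parts) < 3:
                    graph.add_node(parts[0])
                    continue
                src, targets = parts[0], parts[2:]
                for tgt in targets:
                    graph.add_edge(src, tgt)
    elif fmt == "edgelist":
        graph = nx.Graph()
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 2:
                    raise ValidationError(
                        f"{path}:{lineno}: expected at least two columns"
                    )
                graph.add_edge(parts[0], parts[1])
    else:
        raise ValidationError(f"unknown network format {fmt!r}")

    n_loops = nx.number_of_selfloops(graph)
    if n_loops:
        graph.remove_edges_from(nx.selfloop_edges(graph))
        logger.info("dropped %d self-loop(s) from %s", n_loops, path)
    if graph.number_of_nodes() == 0:
        raise ValidationError(f"network file {path} yields an empty graph")
    return graph


def load_expression(path) -> pd.DataFrame:
    """Read a gene x sample expression table (TSV/CSV) or MTX triplet.

    For MTX input, row and column name files with the same stem and suffixes
    ``.rows.txt`` / ``.cols.txt`` are expected next to the matrix.
    """
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        from scipy.io import mmread

        mat = mmread(path)
        if sp.issparse(mat):
            mat = mat.toarray()
        stem = str(path)[: -len(path.suffix)]
        rows = Path(stem + ".rows.txt").read_text().split()
        cols = Path(stem + ".cols.txt").read_text().split()
        return pd.DataFrame(np.asarray(mat), index=rows, columns=cols)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def load_mapping(path) -> pd.DataFrame:
    """Read a two-column gene→protein mapping table (TSV)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError("mapping table must have two columns (gene, protein)")
    df = df.iloc[:, :2]
    df.columns = ["gene", "protein"]
    return df


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def match_expression(
    graph: nx.Graph,
    expression: Mapping[str, float] | pd.Series,
    mapping: pd.DataFrame | None = None,
    pseudocount: float = 0.0,
) -> MatchedNetwork:
    """Match a gene-level expression profile onto the PIN.

    Gene identifiers are translated to protein identifiers via ``mapping``
    (identity on shared identifiers when absent).  When several genes map to
    one protein their expression values are averaged.  Nodes without matched
    expression are removed and the graph is restricted to the largest
    connected component of what remains.
    """
    if isinstance(expression, Mapping):
        expression = pd.Series(expression, dtype=float)
    expression = expression.astype(float)
    if np.any(expression.values < 0):
        bad = list(expression.index[expression.values < 0])
        raise PositivityError(f"negative expression for genes: {bad[:10]}")

    if mapping is not None:
        translated = pd.DataFrame(
            {
                "protein": mapping["protein"].values,
                "value": expression.reindex(mapping["gene"].values).values,
            }
        ).dropna()
        per_protein = translated.groupby("protein")["value"].mean()
    else:
        per_protein = expression.groupby(level=0).mean()

    if pseudocount:
        per_protein = per_protein + pseudocount

    nodes = [str(v) for v in graph.nodes]
    matched = [v for v in nodes if v in per_protein.index]
    if len(matched) < 3:
        raise ValidationError(
            f"only {len(matched)} graph nodes have matched expression; need >= 3"
        )

    sub = graph.subgraph(matched)
    lcc = max(nx.connected_components(sub), key=len)
    if len(lcc) < 3:
        raise ValidationError(
            f"largest matched connected component has {len(lcc)} nodes; need >= 3"
        )
    keep = sorted(lcc)
    sub = graph.subgraph(keep)

    x = per_protein.reindex(keep).values
    nonpos = [keep[i] for i in np.flatnonzero(~(x > 0))]
    if nonpos:
        raise PositivityError(
            f"matched expression not strictly positive for nodes: {nonpos[:10]}"
        )

    adj = nx.to_scipy_sparse_array(sub, nodelist=keep, format="csr", dtype=float)
    adj = sp.csr_matrix(adj)
    adj.data[:] = 1.0
    return MatchedNetwork(tuple(keep), adj, x)


# ---------------------------------------------------------------------------
# weighted operators
# ---------------------------------------------------------------------------

def weighted_adjacency(net: MatchedNetwork) -> EdgeField:
    """Mass-action edge weights W(x)_ij = x_i * x_j on the edges."""
    x = net.expression
    e = net.edge_index
    return EdgeField(e, x[e[:, 0]] * x[e[:, 1]])


def transition_matrix(net: MatchedNetwork) -> sp.csr_matrix:
    """Row-stochastic random-walk operator p_ij = a_ij x_j / sum_k a_ik x_k."""
    x = net.expression
    row_mass = np.asarray(net.adjacency @ x).ravel()
    assert np.all(row_mass > 0), "connected MatchedNetwork cannot have a zero row"
    P = net.adjacency @ sp.diags(x)
    P = sp.diags(1.0 / row_mass) @ P
    return sp.csr_matrix(P)


def stationary_distribution(net: MatchedNetwork) -> np.ndarray:
    """Closed-form stationary distribution pi_i ∝ x_i * sum_j a_ij x_j."""
    x = net.expression
    strength = x * np.asarray(net.adjacency @ x).ravel()
    return strength / strength.sum()
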