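"""Per-subject weighted graphs and nodal graph-theory metrics.

Each subject's normalized (or combined-frequency) connectivity map is
thresholded to its strongest edges and treated as a weighted undirected
graph.  Connection strength is interpreted as proximity: path-based
metrics use distances equal to the inverse connectivity weight, so
stronger amplitude-amplitude coupling means shorter paths.

Six nodal metrics characterize each network:

* degree - number of retained incident edges (binary; the one
  unweighted metric),
* betweenness centrality - fraction of shortest paths through a node,
* eccentricity - maximal shortest-path distance to any reachable node,
* nodal global efficiency - mean inverse shortest-path distance to all
  other nodes,
* local efficiency - mean inverse shortest-path distance within the
  neighbor-induced subgraph,
* clustering coefficient - Onnela geometric-mean weighted triangle
  density around the node.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path

from .connectivity import ConnectivityMatrix, edge_pairs, n_edges

__all__ = [
    "METRICS",
    "SubjectGraph",
    "threshold_individual",
    "shortest_path_distances",
    "node_metrics",
    "feature_table",
    "pooled_features",
]

logger = logging.getLogger(__name__)

#: Metric column blocks, in fixed output order.
METRICS = (
    "degree",
    "betweenness",
    "eccentricity",
    "global_efficiency",
    "local_efficiency",
    "clustering",
)


@dataclass
class SubjectGraph:
    """A thresholded weighted undirected graph for one subject.

    ``edges`` is (n_retained, 2) int node pairs (i < j) and ``weights``
    the corresponding connectivity values.  Path computations use
    distances 1/w and silently exclude nonpositive-weight edges (they
    still count toward degree).
    """

    subject_id: str
    n_nodes: int
    edges: np.ndarray
    weights: np.ndarray
    fraction: float
    mode: str  # "thresholded" | "unthresholded"

    @property
    def n_retained(self) -> int:
        return self.edges.shape[0]

    def positive_edges(self) -> tuple[np.ndarray, np.ndarray]:
        keep = self.weights > 0
        return self.edges[keep], self.weights[keep]

    def adjacency(self, positive_only: bool = False) -> np.ndarray:
        """Dense symmetric weight matrix of the retained edges."""
        a = np.zeros((self.n_nodes, self.n_nodes))
        e, w = (self.positive_edges() if positive_only
                else (self.edges, self.weights))
        a[e[:, 0], e[:, 1]] = w
        a[e[:, 1], e[:, 0]] = w
        return a


def threshold_individual(
    m: ConnectivityMatrix, fraction: float = 0.20
) -> SubjectGraph:
    """Keep the top-``fraction`` strongest edges of one subject's map.

    Exactly ceil(fraction * E) edges are retained; ties are broken by
    lexicographic edge index, so the selection is deterministic.
    ``fraction=1`` gives the unthresholded graph.  Nonpositive retained
    weights (possible in unthresholded mode) are logged; they are kept
    for degree counting but excluded from path-based metrics.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    ev = m.edge_vector()
    E = ev.size
    k = int(np.ceil(fraction * E))
    # stable sort on -value preserves index order among exact ties
    order = np.argsort(-ev, kind="stable")[:k]
    order = np.sort(order)
    i, j = edge_pairs(m.n_nodes)
    edges = np.column_stack([i[order], j[order]])
    weights = ev[order]
    n_nonpos = int((weights <= 0).sum())
    if n_nonpos:
        logger.warning(
            "subject %s: %d retained edge(s) with nonpositive weight; "
            "excluded from path computations",
            m.subject_id, n_nonpos,
        )
    return SubjectGraph(
        subject_id=m.subject_id,
        n_nodes=m.n_nodes,
        edges=edges,
        weights=weights,
        fraction=fraction,
        mode="thresholded" if fraction < 1 else "unthresholded",
    )


def shortest_path_distances(g: SubjectGraph) -> np.ndarray:
    """All-pairs shortest-path distances over edge lengths 1/weight.

    Unreachable pairs get ``inf``; the diagonal is 0.  Only
    positive-weight edges carry distance.
    """
    e, w = g.positive_edges()
    n = g.n_nodes
    if e.shape[0] == 0:
        d = np.full((n, n), np.inf)
        np.fill_diagonal(d, 0.0)
        return d
    lengths = 1.0 / w
    a = csr_array(
        (
            np.concatenate([lengths, lengths]),
            (
                np.concatenate([e[:, 0], e[:, 1]]),
                np.concatenate([e[:, 1], e[:, 0]]),
            ),
        ),
        shape=(n, n),
    )
    return shortest_path(a, method="D", directed=False)


def _positive_graph(g: SubjectGraph) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(range(g.n_nodes))
    e, w = g.positive_edges()
    G.add_weighted_edges_from(
        (int(a), int(b), float(wt)) for (a, b), wt in zip(e, w)
    )
    return G


def node_metrics(g: SubjectGraph) -> pd.DataFrame:
    """The six nodal metrics for one subject graph.

    Returns a (n_nodes x 6) DataFrame with columns :data:`METRICS`.
    Degenerate nodes get defined defaults: isolated nodes have
    eccentricity 0, and nodes with fewer than two neighbors have
    clustering and local efficiency 0.
    """
    n = g.n_nodes
    out = pd.DataFrame(
        0.0, index=pd.RangeIndex(n, name="node"), columns=list(METRICS)
    )

    # degree counts every retained edge, including nonpositive weights
    deg = np.zeros(n)
    np.add.at(deg, g.edges[:, 0], 1)
    np.add.at(deg, g.edges[:, 1], 1)
    out["degree"] = deg

    d = shortest_path_distances(g)
    finite = np.isfinite(d)

    # eccentricity within the node's connected component
    dmax = np.where(finite, d, -np.inf).max(axis=1)
    out["eccentricity"] = np.where(np.isfinite(dmax), dmax, 0.0)

    # nodal global efficiency: unreachable pairs contribute 0
    with np.errstate(divide="ignore"):
        inv = np.where(finite, 1.0 / np.where(d > 0, d, np.inf), 0.0)
    out["global_efficiency"] = inv.sum(axis=1) / max(n - 1, 1)

    G = _positive_graph(g)

    # betweenness, normalized by (n-1)(n-2)/2 so values are fractions;
    # networkx interprets edge weight as length, so feed 1/w distances
    Gd = nx.Graph()
    Gd.add_nodes_from(G.nodes)
    Gd.add_weighted_edges_from(
        (u, v, 1.0 / dat["weight"]) for u, v, dat in G.edges(data=True)
    )
    bw = nx.betweenness_centrality(Gd, weight="weight",
                                   normalized=True, endpoints=False)
    out["betweenness"] = [bw[v] for v in range(n)]

    # Onnela weighted clustering on connectivity weights (not inverses)
    cl = nx.clustering(G, weight="weight")
    out["clustering"] = [cl[v] for v in range(n)]

    # local efficiency on the neighbor-induced subgraph, 1/w distances
    adj = g.adjacency(positive_only=True)
    leff = np.zeros(n)
    for v in range(n):
        nbrs = np.nonzero(adj[v])[0]
        if nbrs.size < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        si, sj = np.nonzero(np.triu(sub, 1))
        if si.size == 0:
            continue
        lens = 1.0 / sub[si, sj]
        sa = csr_array(
            (
                np.concatenate([lens, lens]),
                (np.concatenate([si, sj]), np.concatenate([sj, si])),
            ),
            shape=(nbrs.size, nbrs.size),
        )
        ds = shortest_path(sa, method="D", directed=False)
        iu = np.triu_indices(nbrs.size, 1)
        with np.errstate(divide="ignore"):
            invs = np.where(np.isfinite(ds[iu]), 1.0 / ds[iu], 0.0)
        leff[v] = invs.sum() / iu[0].size
    out["local_efficiency"] = leff
    return out


def feature_table(
    maps: Sequence[ConnectivityMatrix],
    fraction: float = 0.20,
    mode: str = "thresholded",
) -> pd.DataFrame:
    """Nodal metrics for every subject map, one row per subject.

    Columns are a MultiIndex (metric, node).  ``mode="unthresholded"``
    skips the top-fraction selection (all edges retained), the check
    that classification does not hinge on edge selection.
    """
    if mode not in ("thresholded", "unthresholded"):
        raise ValueError(f"unknown mode {mode!r}")
    frac = fraction if mode == "thresholded" else 1.0
    n = maps[0].n_nodes
    rows = []
    ids = []
    for m in maps:
        if m.n_nodes != n:
            raise ValueError("all maps must share the node count")
        tab = node_metrics(threshold_individual(m, fraction=frac))
        rows.append(tab.to_numpy().T.ravel())  # metric-major blocks
        ids.append(m.subject_id)
    cols = pd.MultiIndex.from_product(
        [list(METRICS), range(n)], names=["metric", "node"]
    )
    return pd.DataFrame(rows, index=pd.Index(ids, name="subject_id"),
                        columns=cols)


def pooled_features(table: pd.DataFrame) -> pd.DataFrame:
    """The 6*n pooled feature block (identity on the full table)."""
    return table.copy()
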