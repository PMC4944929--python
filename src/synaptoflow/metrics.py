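"""Node/link centrality and path statistics for weighted connectome graphs.

Degree here comes in two flavours: the unweighted degree (link count) and the
weighted degree, or strength, k_i = Σ_j A(i,j).  Betweenness centrality counts
the all-pairs shortest paths traversing a node (nBC) or a link (eBC), with
fractional credit for tied geodesics; counts are over unordered node pairs and
are unnormalized by default, with path endpoints excluded from nBC.  On the
weighted network a link of weight w has length 1/w, so heavy links are short.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .ingest import WeightedGraph

__all__ = [
    "NodeMetrics",
    "EdgeMetrics",
    "PathCensus",
    "weighted_degree",
    "betweenness",
    "shortest_path_census",
    "degree_distribution",
    "fit_log_slope",
]


@dataclass
class NodeMetrics:
    """Per-node degree, strength and (optionally) betweenness."""

    node_ids: np.ndarray
    degree: np.ndarray          # unweighted link count
    strength: np.ndarray        # weighted degree k_i
    nbc: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {
            "node": self.node_ids,
            "degree": self.degree,
            "k": self.strength,
        }
        if self.nbc is not None:
            data["nBC"] = self.nbc
        return pd.DataFrame(data)


@dataclass
class EdgeMetrics:
    """Per-link edge betweenness, as a tidy (cell_i, cell_j, weight, eBC) table."""

    edges: pd.DataFrame


@dataclass
class PathCensus:
    """Counts of connected ordered node pairs by geodesic hop length."""

    counts: dict                # length -> ordered-pair count
    n_disconnected: int         # ordered pairs with no path
    n_nodes: int

    @property
    def n_connected(self) -> int:
        return int(sum(self.counts.values()))

    def percentages(self) -> dict:
        total = self.n_connected
        return {l: 100.0 * c / total for l, c in self.counts.items()}


def weighted_degree(graph: WeightedGraph) -> NodeMetrics:
    """Unweighted degree (nonzero count per row) and strength (row sum)."""
    w = graph.weights
    return NodeMetrics(
        node_ids=graph.node_ids.copy(),
        degree=np.count_nonzero(w, axis=1),
        strength=w.sum(axis=1),
    )


def betweenness(
    graph: WeightedGraph,
    use_weights: bool = False,
    length_rule: str = "inverse_weight",
    normalized: bool = False,
) -> tuple[NodeMetrics, EdgeMetrics]:
    """Node and edge betweenness via Brandes' accumulation.

    Unordered-pair counting; endpoints excluded for nBC (a path contributes
    to the interior nodes it traverses and to every link on it).  With
    ``use_weights`` the geodesics minimize summed link length, where
    ``inverse_weight`` sets length = 1/weight.
    """
    if length_rule not in ("inverse_weight", "unit"):
        raise ValueError(f"unknown length_rule {length_rule!r}")
    if use_weights and length_rule == "inverse_weight" and (
        graph.weights < 0
    ).any():
        i, j = np.argwhere(graph.weights < 0)[0]
        raise ValueError(
            f"link ({graph.node_ids[i]},{graph.node_ids[j]}) has nonpositive "
            "weight; cannot take inverse-weight length"
        )
    g = graph.to_networkx(use_weights=True)
    weight_key = None
    if use_weights and length_rule == "inverse_weight":
        for u, v, d in g.edges(data=True):
            if d["weight"] <= 0:
                raise ValueError(
                    f"link ({u},{v}) has nonpositive weight {d['weight']}; "
                    "cannot take inverse-weight length"
                )
            d["length"] = 1.0 / d["weight"]
        weight_key = "length"

    nbc = nx.betweenness_centrality(g, normalized=normalized, weight=weight_key)
    ebc = nx.edge_betweenness_centrality(g, normalized=normalized,
                                         weight=weight_key)
    node_metrics = weighted_degree(graph)
    node_metrics.nbc = np.array([nbc[int(v)] for v in graph.node_ids])

    edges = graph.edge_list()
    edges["eBC"] = [
        ebc.get((int(i), int(j)), ebc.get((int(j), int(i)), 0.0))
        for i, j in zip(edges["cell_i"], edges["cell_j"])
    ]
    return node_metrics, EdgeMetrics(edges=edges)


def shortest_path_census(graph: WeightedGraph) -> PathCensus:
    """Census of geodesic hop lengths over the unweighted topology.

    Ordered-pair counting: each connected pair (s, t), s ≠ t, is counted in
    both directions; disconnected ordered pairs are tallied separately.
    """
    n = graph.n_nodes
    adj = csr_matrix((graph.weights > 0).astype(np.int8))
    dist = shortest_path(adj, method="D", unweighted=True, directed=False)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    lengths = dist[finite].astype(np.int64)
    counts = {int(l): int(c) for l, c in zip(*np.unique(lengths,
                                                        return_counts=True))}
    n_disconnected = int(off.sum() - finite.sum())
    return PathCensus(counts=counts, n_disconnected=n_disconnected, n_nodes=n)


def degree_distribution(
    metrics: NodeMetrics,
    binning: str = "log",
    n_bins: int = 20,
    bin_width: float = 1.0,
    use_strength: bool = True,
) -> pd.DataFrame:
    """Histogram of (weighted) degrees.

    Zero-degree nodes are excluded from the bins and reported via the
    ``n_zero`` frame attribute (log bins cannot hold them).  Linear binning
    uses half-open bins of ``bin_width`` centred on multiples of the width,
    so integer degrees with width 1 give per-value counts.
    """
    values = metrics.strength if use_strength else metrics.degree.astype(float)
    n_zero = int(np.sum(values == 0))
    pos = values[values > 0]
    if len(pos) == 0:
        out = pd.DataFrame(columns=["bin_lo", "bin_hi", "center", "count"])
        out.attrs["n_zero"] = n_zero
        return out
    if binning == "log":
        edges = np.logspace(
            np.log10(pos.min()) - 1e-9, np.log10(pos.max()) + 1e-9, n_bins + 1
        )
    elif binning == "linear":
        lo = bin_width * np.floor(pos.min() / bin_width + 0.5) - bin_width / 2
        edges = np.arange(lo, pos.max() + bin_width, bin_width)
    else:
        raise ValueError(f"unknown binning {binning!r}")
    counts, edges = np.histogram(pos, bins=edges)
    out = pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "center": np.sqrt(edges[:-1] * edges[1:])
            if binning == "log"
            else (edges[:-1] + edges[1:]) / 2,
            "count": counts,
        }
    )
    out.attrs["n_zero"] = n_zero
    return out


def fit_log_slope(hist: pd.DataFrame) -> float:
    """Least-squares slope of log10(count) vs log10(degree) on occupied bins."""
    occ = hist[hist["count"] > 0]
    if len(occ) < 2:
        raise ValueError("need at least two occupied bins to fit a slope")
    slope, _ = np.polyfit(np.log10(occ["center"]), np.log10(occ["count"]), 1)
    return float(slope)
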