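"""Graph layouts and figure rendering.

The spectral distance embedding (SDE) lays the graph out so that Euclidean
distances between drawn nodes track graph-theoretic distances (hop counts):
||x_i − x_j|| ≈ D_ij.  It is computed as classical multidimensional scaling —
double-center −½D², take the top eigenpairs with positive eigenvalues, and
scale eigenvectors by the square roots of their eigenvalues — which solves
the global least-squares problem in the spectral sense; the residual stress
Σ(||x_i−x_j|| − D_ij)² is reported for audit.  Anatomical layouts instead
place one axis at a class-assigned depth (bipolar cells shallow, ganglion
cells deep) and keep soma plane coordinates on the others.

Rendering draws module-colored, class-shaped node markers with the strong
links of a chosen focus set, optionally with module hulls and centroids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .ingest import CellCatalog, ConfigError, WeightedGraph

__all__ = [
    "DistanceMatrix",
    "LayoutCoords",
    "graph_distances",
    "sde_layout",
    "anatomical_layout",
    "strong_link_subgraph",
    "render_view",
]

#: Default anatomical layer depth per cell class (bipolar input side at 0.1,
#: ganglion output side at 0.9).
DEFAULT_LAYER_DEPTHS = {
    "cBC": 0.1,
    "rBC": 0.1,
    "other": 0.3,
    "NFac": 0.5,
    "WFac": 0.5,
    "OffSAC": 0.5,
    "OnSAC": 0.5,
    "GC": 0.9,
}


@dataclass
class DistanceMatrix:
    """Symmetric geodesic hop counts; np.inf marks disconnected pairs."""

    node_ids: np.ndarray
    D: np.ndarray


@dataclass
class LayoutCoords:
    """Per-node layout positions (2-D or 3-D)."""

    node_ids: np.ndarray
    coords: np.ndarray
    method: str
    stress: float | None = None
    embedded: np.ndarray | None = None   # mask: True if in the main embedding

    def coords_of(self, node_id) -> np.ndarray:
        idx = np.flatnonzero(self.node_ids == int(node_id))
        if not len(idx):
            raise KeyError(node_id)
        return self.coords[idx[0]]


def graph_distances(graph: WeightedGraph) -> DistanceMatrix:
    """All-pairs hop counts over the unweighted topology (BFS)."""
    adj = csr_matrix((graph.weights > 0).astype(np.int8))
    dist = shortest_path(adj, method="D", unweighted=True, directed=False)
    return DistanceMatrix(node_ids=graph.node_ids.copy(), D=dist)


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    # determinism: make the largest-magnitude coordinate of each axis positive
    for d in range(coords.shape[1]):
        col = coords[:, d]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            coords[:, d] = -col
    return coords


def sde_layout(dm: DistanceMatrix, dims: int = 2) -> LayoutCoords:
    """Classical MDS of the geodesic distance matrix.

    The layout is computed on the largest connected component (the only block
    with finite mutual distances); remaining nodes are placed on a display
    ring at 1.2× the embedding radius and flagged via ``embedded``.
    """
    if dims not in (2, 3):
        raise ValueError("dims must be 2 or 3")
    D = dm.D
    n = D.shape[0]
    finite = np.isfinite(D)
    n_comp, comp = connected_components(csr_matrix(finite & ~np.eye(n, dtype=bool)))
    # nodes isolated in the distance structure form their own components
    sizes = np.bincount(comp, minlength=n_comp)
    main = comp == np.argmax(sizes)
    Dm = D[np.ix_(main, main)]

    m = Dm.shape[0]
    J = np.eye(m) - np.ones((m, m)) / m
    B = -0.5 * J @ (Dm**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10
    use = min(dims, int(pos.sum()))
    if use < dims:
        warnings.warn(
            f"only {use} positive eigenvalues; returning {use}-D embedding "
            f"padded with zeros"
        )
    X = np.zeros((m, dims))
    X[:, :use] = evecs[:, :use] * np.sqrt(evals[:use])
    X = _fix_signs(X)

    diff = X[:, None, :] - X[None, :, :]
    dist_emb = np.sqrt((diff**2).sum(-1))
    iu = np.triu_indices(m, k=1)
    stress = float(((dist_emb[iu] - Dm[iu]) ** 2).sum())

    coords = np.zeros((n, dims))
    coords[main] = X
    rest = np.flatnonzero(~main)
    if len(rest):
        radius = 1.2 * max(np.sqrt((X**2).sum(1)).max(), 1.0)
        theta = 2 * np.pi * np.arange(len(rest)) / len(rest)
        ring = np.zeros((len(rest), dims))
        ring[:, 0] = radius * np.cos(theta)
        ring[:, 1] = radius * np.sin(theta)
        coords[rest] = ring
    return LayoutCoords(
        node_ids=dm.node_ids.copy(),
        coords=coords,
        method=f"sde-{dims}d",
        stress=stress,
        embedded=main,
    )


def anatomical_layout(
    catalog: CellCatalog,
    depth_by_class: dict | None = None,
    plane_axes: tuple = ("y", "z"),
) -> LayoutCoords:
    """Layer depth on the first axis, soma plane coordinates on the others."""
    depths = dict(DEFAULT_LAYER_DEPTHS)
    if depth_by_class:
        depths.update(depth_by_class)
    classes = catalog.table["cell_class"]
    unmapped = sorted(set(classes) - set(depths))
    if unmapped:
        raise ConfigError(f"no layer depth configured for class(es) {unmapped}")
    coords = np.column_stack(
        [
            classes.map(depths).to_numpy(dtype=float),
            catalog.table[plane_axes[0]].to_numpy(dtype=float),
            catalog.table[plane_axes[1]].to_numpy(dtype=float),
        ]
    )
    return LayoutCoords(
        node_ids=catalog.ids.copy(), coords=coords, method="anatomical"
    )


def strong_link_subgraph(
    graph: WeightedGraph, focus_nodes, weight_min: float
) -> WeightedGraph:
    """Links incident to a focus node with weight strictly above ``weight_min``.

    The returned graph contains the focus nodes, every partner reached by a
    kept link, and exactly those links (links between two non-focus partners
    are not included).
    """
    focus_idx = np.array([graph.index_of(v) for v in focus_nodes], dtype=np.intp)
    n = graph.n_nodes
    keep = np.zeros((n, n), dtype=bool)
    strong = graph.weights > weight_min
    keep[focus_idx, :] = strong[focus_idx, :]
    keep |= keep.T
    touched = keep.any(axis=1)
    touched[focus_idx] = True
    sub_w = np.where(keep, graph.weights, 0.0)[np.ix_(touched, touched)]
    return WeightedGraph(
        node_ids=graph.node_ids[touched],
        weights=sub_w,
        threshold_used=graph.threshold_used,
    )


_CLASS_MARKERS = {
    "GC": "*",
    "NFac": "o",
    "WFac": "o",
    "OffSAC": "^",
    "OnSAC": "v",
    "cBC": "D",
    "rBC": "s",
    "other": "P",
}

_MODULE_CMAP = "tab20"


def render_view(
    coords: LayoutCoords,
    subgraph: WeightedGraph,
    partition=None,
    catalog: CellCatalog | None = None,
    out_path=None,
    show_hulls: bool = False,
    hull_geometry=None,
    figsize: tuple = (8.0, 8.0),
    dpi: int = 150,
    axes: tuple = (0, 1),
):
    """Render a module-colored strong-link view to a static image.

    Nodes without coordinates are omitted with a warning.  Deterministic
    given identical inputs and style settings.
    """
    fig, ax = plt.subplots(figsize=figsize, dpi=dpi)
    have = set(int(v) for v in coords.node_ids)
    missing = [int(v) for v in subgraph.node_ids if int(v) not in have]
    if missing:
        warnings.warn(f"{len(missing)} nodes lack coordinates and are omitted")
    drawn = [int(v) for v in subgraph.node_ids if int(v) in have]
    pos = {v: coords.coords_of(v)[list(axes)] for v in drawn}

    edges = subgraph.edge_list()
    wmax = edges["weight"].max() if len(edges) else 1.0
    for _, row in edges.iterrows():
        i, j = int(row["cell_i"]), int(row["cell_j"])
        if i in pos and j in pos:
            lw = 0.3 + 1.7 * np.log1p(row["weight"]) / np.log1p(wmax)
            ax.plot(
                [pos[i][0], pos[j][0]], [pos[i][1], pos[j][1]],
                color="0.6", lw=lw, zorder=1,
            )

    cmap = matplotlib.colormaps[_MODULE_CMAP]
    for v in drawn:
        marker = "o"
        if catalog is not None:
            marker = _CLASS_MARKERS.get(catalog.class_of(v), "o")
        color = "C0"
        if partition is not None:
            color = cmap((partition.as_dict().get(v, 0) - 1) % 20)
        ax.scatter(*pos[v], marker=marker, s=40, color=color, zorder=2,
                   edgecolors="black", linewidths=0.3)

    if show_hulls and hull_geometry is not None:
        for m, hull in hull_geometry.hulls.items():
            if hull is None:
                continue
            xs, ys = hull.exterior.xy
            ax.plot(xs, ys, color=cmap((m - 1) % 20), lw=1.0, zorder=0)
            c = hull.centroid
            ax.plot(c.x, c.y, "+", color=cmap((m - 1) % 20), ms=10)

    ax.set_aspect("equal")
    ax.set_xticks([])
    ax.set_yticks([])
    if out_path is not None:
        fig.savefig(out_path, metadata={"Software": "synaptoflow"})
        plt.close(fig)
        return out_path
    return fig
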