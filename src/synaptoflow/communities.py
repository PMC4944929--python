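"""Flow-based and structural module detection on weighted undirected graphs.

The flow decomposition follows the map-equation framework: a random walker on
the weighted undirected network visits node i with stationary probability
p_i = k_i / Σ k (strength-proportional; no teleportation is needed for an
undirected walk).  A two-level partition M of the nodes is scored by the
average per-step description length, in bits,

    L(M) = q↷ H(Q) + Σ_m (p_m∘ + q_m) H(P_m),

where q_m is the probability of exiting module m (boundary link weight over
total strength), q↷ = Σ_m q_m, H(Q) the entropy of the normalized exit
probabilities, p_m∘ the total visit probability inside m, and H(P_m) the
entropy of the module's exit plus within-module visit rates normalized by
(p_m∘ + q_m).  Minimizing L over partitions yields modules in which the
walker dwells long: a single-module partition costs exactly the entropy of
{p_i}, and splitting pays for the module index book only when within-module
dwell outweighs the exit bookkeeping.  All logarithms are base 2.

The search is a seeded greedy node-move / module-aggregation scheme
(Louvain-style) with restarts; structural alternatives (Newman-Girvan
divisive, greedy modularity agglomeration, spectral clustering of the graph
Laplacian or modularity matrix) and the standard quality/role metrics
(Newman's Q, participation coefficients, adjusted Rand similarity) round out
the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .ingest import CellCatalog, WeightedGraph

__all__ = [
    "Partition",
    "FlowSummary",
    "stationary_flow",
    "codelength",
    "infomap_partition",
    "modularity_Q",
    "girvan_newman",
    "cnm_agglomerative",
    "spectral_partition",
    "participation_coefficients",
    "module_flow_table",
    "partition_similarity",
]


@dataclass
class Partition:
    """Module assignment: integer label ≥ 1 per node."""

    node_ids: np.ndarray
    labels: np.ndarray
    method: str = ""
    seed: int | None = None
    trials: int | None = None

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.node_ids) != len(self.labels):
            raise ValueError("node_ids and labels length mismatch")

    @property
    def n_modules(self) -> int:
        return len(np.unique(self.labels))

    def as_dict(self) -> dict:
        return {int(v): int(l) for v, l in zip(self.node_ids, self.labels)}

    def labels_for(self, node_ids) -> np.ndarray:
        lut = self.as_dict()
        try:
            return np.array([lut[int(v)] for v in node_ids], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"node {exc.args[0]} missing from partition") from None

    def relabel_contiguous(self) -> "Partition":
        _, new = np.unique(self.labels, return_inverse=True)
        return Partition(self.node_ids, new + 1, self.method, self.seed,
                         self.trials)


@dataclass
class FlowSummary:
    """Random-walk visit rates and per-module flow bookkeeping."""

    node_ids: np.ndarray
    p: np.ndarray                       # per-node visit rates, Σ = 1
    module_flow: dict | None = None     # label -> p_m∘
    module_exit: dict | None = None     # label -> q_m
    total_exit: float | None = None     # q↷
    codelength: float | None = None     # bits

    def p_of(self, node_id) -> float:
        idx = np.flatnonzero(self.node_ids == int(node_id))
        if not len(idx):
            raise KeyError(node_id)
        return float(self.p[idx[0]])


def _plogp(x) -> float:
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = x[pos] * np.log2(x[pos])
    return float(out.sum()) if out.ndim else float(out)


def stationary_flow(graph: WeightedGraph) -> FlowSummary:
    """Stationary visit rates p_i = k_i / Σ k of the undirected weighted walk.

    Nodes without links get p_i = 0 (downstream they live in singleton
    modules and contribute no flow).
    """
    k = graph.strength()
    total = k.sum()
    if total <= 0:
        raise ValueError("graph has no links; stationary flow undefined")
    return FlowSummary(node_ids=graph.node_ids.copy(), p=k / total)


def codelength(graph: WeightedGraph, partition: Partition) -> float:
    """Two-level map-equation description length of ``partition``, in bits."""
    labels = partition.labels_for(graph.node_ids)
    k = graph.strength()
    total = k.sum()
    if total <= 0:
        raise ValueError("graph has no links")
    p = k / total

    uniq = np.unique(labels)
    sum_plogp_q = 0.0
    sum_plogp_pq = 0.0
    q_tot = 0.0
    for m in uniq:
        mask = labels == m
        p_m = p[mask].sum()
        if p_m == 0 and mask.sum() > 0:
            # module of isolated nodes: no flow, no code
            continue
        # exit probability: boundary link weight over total strength
        cut = graph.weights[np.ix_(mask, ~mask)].sum()
        q_m = cut / total
        q_tot += q_m
        sum_plogp_q += _plogp(np.array([q_m]))
        sum_plogp_pq += _plogp(np.array([p_m + q_m]))
    sum_plogp_p = _plogp(p)
    L = _plogp(np.array([q_tot])) - 2 * sum_plogp_q + sum_plogp_pq - sum_plogp_p
    return float(L)


# ---------------------------------------------------------------------------
# greedy two-level search


def _louvain_min_codelength(adj, selfw, pflow, const_term, rng):
    """One restart of greedy node-move + module-aggregation minimizing L.

    ``adj`` is a list of dicts {neighbour: normalized link weight ω}, with
    Σ over unordered links 2ω + Σ selfw = 1 - (flow on absent self loops);
    pflow are node visit rates.  Returns (membership array, L).
    """

    def plogp(x):
        return x * np.log2(x) if x > 0 else 0.0

    n0 = len(pflow)
    node_of = [np.array([v]) for v in range(n0)]  # supernode -> original nodes
    membership0 = np.arange(n0)

    while True:
        n = len(adj)
        member = np.arange(n)
        deg = np.array([sum(d.values()) for d in adj])  # ω to others
        P = pflow.copy()
        Q = deg.copy().astype(float)
        q_tot = Q.sum()
        S_q = sum(plogp(q) for q in Q)
        S_pq = sum(plogp(P[i] + Q[i]) for i in range(n))

        improved_any = False
        for _sweep in range(100):
            moved = 0
            for v in rng.permutation(n):
                a = member[v]
                # link weight from v to each neighbouring module
                w_to = {}
                for u, w in adj[v].items():
                    w_to[member[u]] = w_to.get(member[u], 0.0) + w
                dv = deg[v]
                pv = pflow[v]
                w_va = w_to.get(a, 0.0)

                # removing v from a
                Qa_new = Q[a] - dv + 2 * w_va
                Pa_new = P[a] - pv
                best_dL = 0.0
                best_b = a
                candidates = [b for b in w_to if b != a]
                candidates.append(-1)  # fresh singleton module
                for b in candidates:
                    if b == -1:
                        Qb, Pb, w_vb = 0.0, 0.0, 0.0
                    else:
                        Qb, Pb = Q[b], P[b]
                        w_vb = w_to.get(b, 0.0)
                    Qb_new = Qb + dv - 2 * w_vb
                    dq = (Qa_new - Q[a]) + (Qb_new - Qb)
                    dS_q = (
                        -plogp(Q[a]) + plogp(Qa_new)
                        - plogp(Qb) + plogp(Qb_new)
                    )
                    dS_pq = (
                        -plogp(P[a] + Q[a]) + plogp(Pa_new + Qa_new)
                        - plogp(Pb + Qb) + plogp(Pb + pv + Qb_new)
                    )
                    dL = (
                        plogp(q_tot + dq) - plogp(q_tot)
                        - 2 * dS_q + dS_pq
                    )
                    if dL < best_dL - 1e-12:
                        best_dL = dL
                        best_b = b
                if best_b != a:
                    b = best_b
                    if b == -1:
                        # allocate a fresh module slot
                        b = len(Q)
                        Q = np.append(Q, 0.0)
                        P = np.append(P, 0.0)
                    w_vb = w_to.get(b, 0.0)
                    Qb_new = Q[b] + dv - 2 * w_vb
                    S_q += (
                        -plogp(Q[a]) + plogp(Qa_new)
                        - plogp(Q[b]) + plogp(Qb_new)
                    )
                    S_pq += (
                        -plogp(P[a] + Q[a]) + plogp(Pa_new + Qa_new)
                        - plogp(P[b] + Q[b]) + plogp(P[b] + pv + Qb_new)
                    )
                    q_tot += (Qa_new - Q[a]) + (Qb_new - Q[b])
                    Q[a], P[a] = Qa_new, Pa_new
                    Q[b], P[b] = Qb_new, P[b] + pv
                    member[v] = b
                    moved += 1
            if moved == 0:
                break
            improved_any = True

        uniq, member = np.unique(member, return_inverse=True)
        n_mod = len(uniq)
        if not improved_any or n_mod == n:
            L = plogp(q_tot) - 2 * S_q + S_pq - const_term
            final = np.empty(n0, dtype=np.int64)
            for sv in range(n):
                final[node_of[sv]] = member[sv]
            return final, float(L)

        # aggregate modules into supernodes and recurse
        new_node_of = [
            np.concatenate([node_of[sv] for sv in np.flatnonzero(member == m)])
            for m in range(n_mod)
        ]
        new_adj = [dict() for _ in range(n_mod)]
        new_selfw = np.zeros(n_mod)
        new_pflow = np.zeros(n_mod)
        for v in range(n):
            mv = member[v]
            new_pflow[mv] += pflow[v]
            new_selfw[mv] += selfw[v]
            for u, w in adj[v].items():
                mu = member[u]
                if mu == mv:
                    if u > v:
                        new_selfw[mv] += w
                else:
                    new_adj[mv][mu] = new_adj[mv].get(mu, 0.0) + w
        adj, selfw, pflow, node_of = new_adj, new_selfw, new_pflow, new_node_of


def infomap_partition(
    graph: WeightedGraph, seed: int = 0, trials: int = 10
) -> tuple[Partition, FlowSummary]:
    """Minimum-codelength two-level partition by seeded greedy search.

    ``trials`` independent restarts with shuffled node orders; the lowest
    codelength wins (ties keep the earliest trial, so results are
    reproducible bit-for-bit given graph, seed and trials).  Nodes without
    links become singleton modules with zero flow, appended after the flow
    modules.  Modules are sorted by total flow descending (ties by smallest
    member ID) and relabeled 1..K.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    k = graph.strength()
    linked = k > 0
    ids_linked = graph.node_ids[linked]
    n = int(linked.sum())
    if n == 0:
        raise ValueError("graph has no links")

    sub = graph.weights[np.ix_(linked, linked)]
    total = sub.sum()
    pflow = sub.sum(axis=1) / total
    iu, ju = np.triu_indices(n, k=1)
    nz = sub[iu, ju] > 0
    adj0 = [dict() for _ in range(n)]
    for i, j, w in zip(iu[nz], ju[nz], sub[iu[nz], ju[nz]] / total):
        adj0[i][j] = w
        adj0[j][i] = w
    selfw0 = np.zeros(n)
    const_term = _plogp(pflow)

    best = None
    root = np.random.default_rng(seed)
    for t in range(trials):
        rng = np.random.default_rng(root.integers(0, 2**31))
        adj = [dict(d) for d in adj0]
        member, L = _louvain_min_codelength(adj, selfw0.copy(), pflow,
                                            const_term, rng)
        if best is None or L < best[1] - 1e-12:
            best = (member, L)
    member, L = best

    # recompute flow bookkeeping on the winning partition
    labels_full = np.zeros(graph.n_nodes, dtype=np.int64)
    labels_full[linked] = member + 1
    next_label = member.max() + 2
    for idx in np.flatnonzero(~linked):
        labels_full[idx] = next_label
        next_label += 1

    partition = Partition(
        node_ids=graph.node_ids.copy(),
        labels=labels_full,
        method="infomap-greedy",
        seed=seed,
        trials=trials,
    )
    partition = _sort_modules_by_flow(graph, partition)
    flow = summarize_flow(graph, partition)
    return partition, flow


def _sort_modules_by_flow(graph: WeightedGraph,
                          partition: Partition) -> Partition:
    """Relabel modules 1..K by total flow descending, ties by smallest ID."""
    k = graph.strength()
    p = k / k.sum()
    labels = partition.labels_for(graph.node_ids)
    order = []
    for m in np.unique(labels):
        mask = labels == m
        order.append((-p[mask].sum(), int(graph.node_ids[mask].min()), m))
    order.sort()
    remap = {m: i + 1 for i, (_, _, m) in enumerate(order)}
    return Partition(
        node_ids=partition.node_ids,
        labels=np.array([remap[l] for l in partition.labels]),
        method=partition.method,
        seed=partition.seed,
        trials=partition.trials,
    )


def summarize_flow(graph: WeightedGraph, partition: Partition) -> FlowSummary:
    """Per-node visit rates plus per-module flow, exit and codelength."""
    flow = stationary_flow(graph)
    labels = partition.labels_for(graph.node_ids)
    total = graph.strength().sum()
    module_flow, module_exit = {}, {}
    for m in np.unique(labels):
        mask = labels == m
        module_flow[int(m)] = float(flow.p[mask].sum())
        module_exit[int(m)] = float(
            graph.weights[np.ix_(mask, ~mask)].sum() / total
        )
    flow.module_flow = module_flow
    flow.module_exit = module_exit
    flow.total_exit = float(sum(module_exit.values()))
    flow.codelength = codelength(graph, partition)
    return flow


# ---------------------------------------------------------------------------
# structural methods


def modularity_Q(graph: WeightedGraph, partition: Partition) -> float:
    """Newman's Q = (1/2W) Σ_ij [A_ij − k_i k_j / 2W] δ(c_i, c_j)."""
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    labels = partition.labels_for(graph.node_ids)
    k = graph.strength()
    two_w = k.sum()
    if two_w <= 0:
        raise ValueError("graph has no links")
    q = 0.0
    for m in np.unique(labels):
        mask = labels == m
        q += graph.weights[np.ix_(mask, mask)].sum() / two_w
        q -= (k[mask].sum() / two_w) ** 2
    return float(q)


def girvan_newman(
    graph: WeightedGraph, target_modules: int, use_weights: bool = False
) -> Partition:
    """Divisive decomposition: iteratively cut the max-eBC link.

    Edge betweenness is recomputed after every removal; ties broken by the
    smallest (i, j).  Stops when the number of connected components reaches
    ``target_modules`` (isolated nodes count as components); if the target
    exceeds the node count a warning is issued and the best achieved
    partition returned.
    """
    g = graph.to_networkx(use_weights=True)
    if use_weights:
        for u, v, d in g.edges(data=True):
            d["length"] = 1.0 / d["weight"]
    weight_key = "length" if use_weights else None
    if target_modules > g.number_of_nodes():
        warnings.warn(
            f"target_modules={target_modules} exceeds node count; "
            "returning all-singletons"
        )
    while (
        nx.number_connected_components(g) < target_modules
        and g.number_of_edges() > 0
    ):
        ebc = nx.edge_betweenness_centrality(g, normalized=False,
                                             weight=weight_key)
        cut = min(
            (e for e, v in ebc.items() if v == max(ebc.values())),
            key=lambda e: tuple(sorted(e)),
        )
        g.remove_edge(*cut)
    labels = np.zeros(graph.n_nodes, dtype=np.int64)
    for m, comp in enumerate(
        sorted(nx.connected_components(g), key=lambda c: min(c)), start=1
    ):
        for v in comp:
            labels[graph.index_of(v)] = m
    return Partition(graph.node_ids.copy(), labels, method="girvan-newman")


def cnm_agglomerative(graph: WeightedGraph) -> Partition:
    """Greedy modularity agglomeration; returns the max-Q dendrogram cut."""
    g = graph.to_networkx(use_weights=True)
    comms = nx.community.greedy_modularity_communities(g, weight="weight")
    labels = np.zeros(graph.n_nodes, dtype=np.int64)
    for m, comp in enumerate(
        sorted((set(c) for c in comms), key=lambda c: min(c)), start=1
    ):
        for v in comp:
            labels[graph.index_of(v)] = m
    return Partition(graph.node_ids.copy(), labels, method="cnm-agglomerative")


def spectral_partition(
    graph: WeightedGraph,
    k: int | None = None,
    basis: str = "laplacian",
    k_range: tuple = (2, 20),
    seed: int = 0,
    n_init: int = 20,
) -> tuple[Partition, pd.DataFrame]:
    """k-means clustering of graph-spectrum eigenvectors.

    ``laplacian``: rows of the eigenvectors of the k smallest nontrivial
    eigenvalues of L = D − A.  ``modularity_matrix``: leading eigenvectors of
    B = A − kkᵀ/2W with positive eigenvalues only.  When ``k`` is None, k is
    scanned over ``k_range`` and the max-Q choice returned along with the
    scan table.  Nodes without links become appended singleton modules.
    """
    if basis not in ("laplacian", "modularity_matrix"):
        raise ValueError(f"unknown basis {basis!r}")
    strength = graph.strength()
    linked = strength > 0
    n = int(linked.sum())
    a = graph.weights[np.ix_(linked, linked)]
    ks = a.sum(axis=1)
    if basis == "laplacian":
        mat = np.diag(ks) - a
        evals, evecs = np.linalg.eigh(mat)
        order = np.argsort(evals)           # smallest first, skip trivial 0
        usable = evecs[:, order[1:]]
    else:
        mat = a - np.outer(ks, ks) / ks.sum()
        evals, evecs = np.linalg.eigh(mat)
        order = np.argsort(evals)[::-1]
        pos = evals[order] > 1e-12
        usable = evecs[:, order[pos]]

    def cluster(kk: int) -> np.ndarray:
        # Laplacian basis: the k-1 nontrivial eigenvectors (the trivial
        # constant vector carries no information for k clusters)
        want = kk - 1 if basis == "laplacian" else kk
        dims = max(1, min(want, usable.shape[1]))
        basis_vecs = usable[:, :dims]
        km = KMeans(n_clusters=kk, n_init=n_init, random_state=seed)
        return km.fit_predict(basis_vecs)

    def to_partition(lab: np.ndarray, kk: int) -> Partition:
        labels = np.zeros(graph.n_nodes, dtype=np.int64)
        labels[linked] = lab + 1
        nxt = lab.max() + 2
        for idx in np.flatnonzero(~linked):
            labels[idx] = nxt
            nxt += 1
        return Partition(graph.node_ids.copy(), labels,
                         method=f"spectral-{basis}-k{kk}", seed=seed)

    if k is not None:
        if not (2 <= k <= n):
            raise ValueError(f"k={k} outside [2, {n}]")
        part = to_partition(cluster(k), k)
        q = modularity_Q(graph, part)
        scan = pd.DataFrame({"k": [k], "Q": [q]})
        return part, scan

    rows, best = [], None
    for kk in range(k_range[0], min(k_range[1], n - 1) + 1):
        part = to_partition(cluster(kk), kk)
        q = modularity_Q(graph, part)
        rows.append({"k": kk, "Q": q})
        if best is None or q > best[1]:
            best = (part, q, kk)
    return best[0], pd.DataFrame(rows)


def participation_coefficients(
    graph: WeightedGraph, partition: Partition
) -> np.ndarray:
    """P_i = 1 − Σ_m (k_im / k_i)²; 0 for isolated nodes.

    k_im is node i's summed link weight into module m.  P_i near 1 means the
    node's links are spread across many modules.
    """
    labels = partition.labels_for(graph.node_ids)
    k = graph.strength()
    p = np.zeros(graph.n_nodes)
    uniq = np.unique(labels)
    k_im = np.stack([graph.weights[:, labels == m].sum(axis=1) for m in uniq],
                    axis=1)
    nz = k > 0
    p[nz] = 1.0 - ((k_im[nz] / k[nz, None]) ** 2).sum(axis=1)
    return p


def module_flow_table(
    flow: FlowSummary,
    partition: Partition,
    catalog: CellCatalog | None = None,
    n_top_classes: int = 2,
) -> pd.DataFrame:
    """Per-module flow/membership table, sorted by total flow descending."""
    labels = partition.labels_for(flow.node_ids)
    rows = []
    for m in np.unique(labels):
        mask = labels == m
        row = {
            "module": int(m),
            "total_flow": float(flow.p[mask].sum()),
            "n_members": int(mask.sum()),
            "min_member_id": int(flow.node_ids[mask].min()),
        }
        if catalog is not None:
            classes = pd.Series(
                [catalog.class_of(v) for v in flow.node_ids[mask]]
            )
            top = classes.value_counts().head(n_top_classes)
            row["key_classes"] = ", ".join(top.index)
        rows.append(row)
    out = pd.DataFrame(rows).sort_values(
        ["total_flow", "min_member_id"], ascending=[False, True]
    )
    return out.drop(columns="min_member_id").reset_index(drop=True)


def nontrivial_modules(
    flow: FlowSummary,
    partition: Partition,
    min_members: int = 15,
    min_flow: float = 0.01,
) -> list:
    """Module labels with more than ``min_members`` members or more than
    ``min_flow`` of the total flow."""
    labels = partition.labels_for(flow.node_ids)
    out = []
    for m in np.unique(labels):
        mask = labels == m
        if mask.sum() > min_members or flow.p[mask].sum() > min_flow:
            out.append(int(m))
    return out


def partition_similarity(p1: Partition, p2: Partition) -> float:
    """Adjusted Rand index between two partitions of the same node set."""
    if sorted(p1.node_ids.tolist()) != sorted(p2.node_ids.tolist()):
        raise ValueError("partitions cover different node sets")
    order = np.argsort(p1.node_ids)
    l1 = p1.labels[order]
    l2 = p2.labels_for(p1.node_ids[order])
    return float(adjusted_rand_score(l1, l2))
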