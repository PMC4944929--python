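"""Contact-list ingestion and weighted-graph construction.

Raw electron-microscopy reconstructions report cell-to-cell *contacts*: each
row is an apposition between two cells with its membrane contact area (μm²)
and a 3-D centroid (μm).  A contact area above a chosen threshold is taken as
evidence of a synapse, and the summed contact area of a cell pair -- expressed
as a multiple of that threshold -- becomes the weight of an undirected network
link.  This module parses contact lists, filters them by area, corrects the
double listing of the same contact in i→j and j→i order, aggregates contacts
into a symmetric weighted adjacency matrix, and reads/writes the dense-CSV
adjacency dialect used for the 950-neuron mouse-retina sample.

The cell catalog maps sequential neuron IDs to cell classes (ganglion cells,
near/wide-field amacrines including the starburst subclasses, cone and rod
bipolar cells, and one-of-a-kind "other" cells) and carries soma coordinates.
Glia are not part of the neuronal network and are dropped with a logged count.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FormatError",
    "ConfigError",
    "ContactTable",
    "WeightedGraph",
    "CellCatalog",
    "DEFAULT_COLUMNS",
    "DEFAULT_CELL_RANGES",
    "read_contact_list",
    "filter_contacts",
    "aggregate_links",
    "read_adjacency",
    "write_adjacency",
    "load_cell_catalog",
    "drop_uncataloged_contacts",
]


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class ConfigError(ValueError):
    """A configuration (column map, ID ranges, parameters) is inconsistent."""


DEFAULT_COLUMNS = {
    "cell_i": "cell_i",
    "cell_j": "cell_j",
    "area": "area",
    "x": "x",
    "y": "y",
    "z": "z",
}

#: Cell-class ID ranges for the 950-neuron mouse retina sample.  Starburst
#: amacrine ranges nest inside the wide-field amacrine block.
DEFAULT_CELL_RANGES = {
    "GC": [(1, 36)],
    "NFac": [(37, 226)],
    "WFac": [(227, 389)],
    "OffSAC": [(260, 274)],
    "OnSAC": [(358, 370)],
    "cBC": [(390, 696)],
    "rBC": [(697, 840)],
    "other": [(841, 950)],
}

#: Classes whose ranges nest inside a parent class range.
NESTED_CLASSES = {"OffSAC": "WFac", "OnSAC": "WFac"}

_CONTACT_FIELDS = ["cell_i", "cell_j", "area", "x", "y", "z"]


@dataclass
class ContactTable:
    """Ordered collection of contact records with filter provenance.

    ``records`` has columns cell_i, cell_j (int), area, x, y, z (float).
    """

    records: pd.DataFrame
    provenance: list = field(default_factory=list)
    n_dropped_self: int = 0
    n_dropped_malformed: int = 0
    malformed_lines: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def with_records(self, records: pd.DataFrame, note: str) -> "ContactTable":
        return ContactTable(
            records=records.reset_index(drop=True),
            provenance=self.provenance + [note],
            n_dropped_self=self.n_dropped_self,
            n_dropped_malformed=self.n_dropped_malformed,
            malformed_lines=list(self.malformed_lines),
        )


@dataclass
class WeightedGraph:
    """Symmetric nonnegative weighted adjacency over neuron IDs.

    Weights are multiples of ``threshold_used`` (μm² of summed contact area
    per unit weight).  The diagonal is zero; A(i,j) == A(j,i).
    """

    node_ids: np.ndarray
    weights: np.ndarray
    threshold_used: float = 1.0

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.node_ids)
        if self.weights.shape != (n, n):
            raise ValueError(
                f"weights shape {self.weights.shape} does not match "
                f"{n} node IDs"
            )
        self._index = {int(v): i for i, v in enumerate(self.node_ids)}

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_links(self) -> int:
        """Number of undirected links (unordered pairs with weight > 0)."""
        return int(np.count_nonzero(np.triu(self.weights, k=1)))

    @property
    def density(self) -> float:
        n = self.n_nodes
        return self.n_links / (n * (n - 1) / 2)

    def index_of(self, node_id: int) -> int:
        try:
            return self._index[int(node_id)]
        except KeyError:
            raise KeyError(f"node ID {node_id} not in graph") from None

    def strength(self) -> np.ndarray:
        """Weighted degree k_i = Σ_j A(i,j) per node."""
        return self.weights.sum(axis=1)

    def edge_list(self) -> pd.DataFrame:
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        m = self.weights[iu, ju] > 0
        return pd.DataFrame(
            {
                "cell_i": self.node_ids[iu[m]],
                "cell_j": self.node_ids[ju[m]],
                "weight": self.weights[iu[m], ju[m]],
            }
        )

    def to_networkx(self, use_weights: bool = True):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(int(v) for v in self.node_ids)
        edges = self.edge_list()
        if use_weights:
            g.add_weighted_edges_from(
                zip(edges["cell_i"], edges["cell_j"], edges["weight"])
            )
        else:
            g.add_edges_from(zip(edges["cell_i"], edges["cell_j"]))
        return g


@dataclass
class CellCatalog:
    """Neuron IDs with class/subtype labels and optional soma coordinates.

    ``table`` columns: id, cell_class (finest label, e.g. OffSAC),
    broad_class (parent class, e.g. WFac), subtype, x, y, z.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self._by_id = self.table.set_index("id")

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    def class_of(self, node_id: int) -> str:
        return str(self._by_id.at[int(node_id), "cell_class"])

    def subtype_of(self, node_id: int) -> str:
        return str(self._by_id.at[int(node_id), "subtype"])

    def ids_of(self, cell_class: str, broad: bool = False) -> np.ndarray:
        col = "broad_class" if broad else "cell_class"
        return self.table.loc[
            self.table[col] == cell_class, "id"
        ].to_numpy()

    def coords(self, axes=("x", "y")) -> pd.DataFrame:
        return self.table.set_index("id")[list(axes)]


# ---------------------------------------------------------------------------
# contact list I/O


def read_contact_list(path, dialect: dict | None = None) -> ContactTable:
    """Parse a contact-list CSV into a :class:`ContactTable`.

    ``dialect`` maps canonical field names (cell_i, cell_j, area, x, y, z) to
    the column names present in the file.  Self-contacts (cell_i == cell_j)
    are dropped and counted; rows with non-numeric required fields are dropped
    and reported with their 1-based file line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    colmap = dict(DEFAULT_COLUMNS)
    if dialect:
        colmap.update(dialect)

    raw = pd.read_csv(path, dtype=str)
    missing = [colmap[f] for f in _CONTACT_FIELDS if colmap[f] not in raw.columns]
    if missing:
        raise FormatError(
            f"{path.name}: missing required column(s) {missing}; "
            f"found {list(raw.columns)}"
        )
    df = raw[[colmap[f] for f in _CONTACT_FIELDS]].copy()
    df.columns = _CONTACT_FIELDS
    for col in _CONTACT_FIELDS:
        df[col] = pd.to_numeric(df[col], errors="coerce")

    bad = df[_CONTACT_FIELDS].isna().any(axis=1)
    # +2: 1-based line numbers and one header line
    malformed_lines = (df.index[bad] + 2).tolist()
    df = df[~bad]

    self_mask = df["cell_i"] == df["cell_j"]
    n_self = int(self_mask.sum())
    df = df[~self_mask]

    df = df.astype({"cell_i": np.int64, "cell_j": np.int64}).reset_index(drop=True)
    notes = [f"read {path} ({len(raw)} rows)"]
    if malformed_lines:
        notes.append(f"dropped {len(malformed_lines)} malformed rows")
    if n_self:
        notes.append(f"dropped {n_self} self-contacts")
    return ContactTable(
        records=df,
        provenance=notes,
        n_dropped_self=n_self,
        n_dropped_malformed=len(malformed_lines),
        malformed_lines=malformed_lines,
    )


def write_contact_list(table: ContactTable, path) -> None:
    table.records.to_csv(path, index=False)


def filter_contacts(
    table: ContactTable, area_threshold: float, strict: bool = False
) -> ContactTable:
    """Keep contacts with area ≥ threshold (or > threshold when ``strict``).

    The inclusive boundary is the default: the area threshold marks the 50%
    synapse-probability point, so boundary contacts are retained.
    """
    if area_threshold <= 0:
        raise ConfigError(f"area_threshold must be > 0, got {area_threshold}")
    op = "gt" if strict else "ge"
    if strict:
        kept = table.records[table.records["area"] > area_threshold]
    else:
        kept = table.records[table.records["area"] >= area_threshold]
    return table.with_records(
        kept, f"filter area {op} {area_threshold} μm²: kept {len(kept)}"
    )


def drop_uncataloged_contacts(
    table: ContactTable, catalog: CellCatalog
) -> tuple[ContactTable, int]:
    """Drop contacts touching IDs absent from the catalog (e.g. glia)."""
    known = set(int(v) for v in catalog.ids)
    df = table.records
    mask = df["cell_i"].isin(known) & df["cell_j"].isin(known)
    n_dropped = int((~mask).sum())
    out = table.with_records(
        df[mask], f"dropped {n_dropped} contacts to uncataloged cells"
    )
    return out, n_dropped


def _dedup_double_listings(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Collapse double listings of the same physical contact.

    A contact reported both as i→j and j→i appears as two rows identical in
    unordered pair, area and coordinates; only one is kept.  Distinct contacts
    between the same pair (different coordinates or areas) all survive.
    """
    lo = np.minimum(df["cell_i"], df["cell_j"])
    hi = np.maximum(df["cell_i"], df["cell_j"])
    key = pd.DataFrame(
        {"lo": lo, "hi": hi, "area": df["area"], "x": df["x"],
         "y": df["y"], "z": df["z"]}
    )
    keep = ~key.duplicated()
    return df[keep], int((~keep).sum())


def aggregate_links(
    table: ContactTable,
    threshold: float,
    filter_mode: str = "per_contact",
    node_ids=None,
    base_threshold: float = 0.08,
    dedup: bool = True,
) -> WeightedGraph:
    """Aggregate contacts into a symmetric weighted adjacency matrix.

    (i,j) and (j,i) listings are pooled by unordered pair; surviving contact
    areas per pair are summed and the total expressed as a multiple of
    ``threshold``.  Under ``per_contact`` mode individual contacts below the
    threshold are removed before summation (so every retained pair has weight
    ≥ 1); under ``per_pair_total`` mode contacts ≥ ``base_threshold`` are
    summed and the pair is kept only if the total reaches ``threshold``.
    """
    if threshold <= 0:
        raise ConfigError(f"threshold must be > 0, got {threshold}")
    if filter_mode not in ("per_contact", "per_pair_total"):
        raise ConfigError(f"unknown filter_mode {filter_mode!r}")
    df = table.records
    if df.empty:
        raise ValueError("contact table is empty")

    n_dups = 0
    if dedup:
        df, n_dups = _dedup_double_listings(df)

    cutoff = threshold if filter_mode == "per_contact" else base_threshold
    df = df[df["area"] >= cutoff]

    lo = np.minimum(df["cell_i"], df["cell_j"]).to_numpy()
    hi = np.maximum(df["cell_i"], df["cell_j"]).to_numpy()
    totals = (
        pd.DataFrame({"lo": lo, "hi": hi, "area": df["area"].to_numpy()})
        .groupby(["lo", "hi"], as_index=False)["area"]
        .sum()
    )
    if filter_mode == "per_pair_total":
        totals = totals[totals["area"] >= threshold]

    if node_ids is None:
        node_ids = np.unique(np.concatenate([totals["lo"], totals["hi"]]))
    node_ids = np.asarray(node_ids, dtype=np.int64)
    index = {int(v): i for i, v in enumerate(node_ids)}
    try:
        ii = np.array([index[int(v)] for v in totals["lo"]], dtype=np.intp)
        jj = np.array([index[int(v)] for v in totals["hi"]], dtype=np.intp)
    except KeyError as exc:
        raise KeyError(
            f"contact references neuron ID {exc.args[0]} absent from the node list"
        ) from None

    n = len(node_ids)
    weights = np.zeros((n, n))
    w = totals["area"].to_numpy() / threshold
    weights[ii, jj] = w
    weights[jj, ii] = w
    graph = WeightedGraph(node_ids=node_ids, weights=weights,
                          threshold_used=threshold)
    graph.n_deduplicated = n_dups
    return graph


# ---------------------------------------------------------------------------
# adjacency matrix I/O (dense CSV dialect)


def read_adjacency(path, symmetry_tol: float = 1e-9) -> WeightedGraph:
    """Read a dense CSV adjacency matrix.

    Accepts a bare N×N numeric matrix (node IDs then default to 1..N) or the
    supplementary-data dialect with a leading header row of node IDs.
    Symmetry is verified to ``symmetry_tol``; asymmetric input is an error
    reporting the worst (i, j) entry.
    """
    raw = pd.read_csv(path, header=None, dtype=str).to_numpy()
    node_ids = None
    first = pd.to_numeric(pd.Series(raw[0]), errors="coerce")
    if raw.shape[0] == raw.shape[1] + 1:
        # header row of node IDs
        node_ids = first.to_numpy()
        if np.isnan(node_ids).any():
            raise FormatError(f"{path}: non-numeric node-ID header row")
        node_ids = node_ids.astype(np.int64)
        raw = raw[1:]
    elif raw.shape[0] == raw.shape[1] and first.isna().any():
        raise FormatError(f"{path}: non-numeric entries in first row")

    if raw.shape[0] != raw.shape[1]:
        raise FormatError(
            f"{path}: adjacency matrix must be square, got {raw.shape}"
        )
    try:
        # numpy's parser is correctly rounded (pandas' fast path is not)
        mat = raw.astype(np.float64)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric value in matrix: {exc}") from None
    if np.isnan(mat).any():
        bad = np.argwhere(np.isnan(mat))[0]
        raise FormatError(f"{path}: non-numeric value at row {bad[0]}, col {bad[1]}")
    asym = np.abs(mat - mat.T)
    worst = np.unravel_index(np.argmax(asym), asym.shape)
    if asym[worst] > symmetry_tol:
        raise FormatError(
            f"{path}: matrix is asymmetric; worst entry at (i,j)="
            f"({worst[0]},{worst[1]}), |A(i,j)-A(j,i)|={asym[worst]:.3g}"
        )
    mat = (mat + mat.T) / 2.0
    np.fill_diagonal(mat, 0.0)
    n = mat.shape[0]
    if node_ids is None:
        node_ids = np.arange(1, n + 1, dtype=np.int64)
    return WeightedGraph(node_ids=node_ids, weights=mat)


def write_adjacency(graph: WeightedGraph, path, header: bool = True) -> None:
    """Write a dense CSV adjacency; values round-trip exactly (17 sig. digits)."""
    with open(path, "w") as fh:
        if header:
            fh.write(",".join(str(int(v)) for v in graph.node_ids) + "\n")
        for row in graph.weights:
            fh.write(",".join(f"{v:.17g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# cell catalog


def _normalize_ranges(ranges) -> dict:
    out = {}
    for name, spans in ranges.items():
        if isinstance(spans, (tuple, list)) and len(spans) == 2 and all(
            isinstance(v, (int, np.integer)) for v in spans
        ):
            spans = [tuple(spans)]
        out[name] = [(int(lo), int(hi)) for lo, hi in spans]
    return out


def load_cell_catalog(
    ranges=None, soma_path=None, soma_df: pd.DataFrame | None = None
) -> CellCatalog:
    """Build a :class:`CellCatalog` from class ID ranges and optional soma CSV.

    ``ranges`` maps class name to (lo, hi) ID spans (YAML path, dict, or None
    for the default 950-neuron retina ranges).  Non-nested ranges must
    partition 1..N without gap or overlap; classes listed in
    :data:`NESTED_CLASSES` (the starburst amacrines) nest inside their parent
    and re-label those IDs while keeping the parent as ``broad_class``.
    """
    if ranges is None:
        ranges = DEFAULT_CELL_RANGES
    elif isinstance(ranges, (str, os.PathLike)):
        with open(ranges) as fh:
            ranges = yaml.safe_load(fh)
    ranges = _normalize_ranges(ranges)

    base = {k: v for k, v in ranges.items() if k not in NESTED_CLASSES}
    n = max(hi for spans in base.values() for _, hi in spans)
    cover = np.zeros(n + 1, dtype=int)
    for spans in base.values():
        for lo, hi in spans:
            cover[lo : hi + 1] += 1
    gaps = np.flatnonzero(cover[1:] == 0) + 1
    overlaps = np.flatnonzero(cover[1:] > 1) + 1
    if len(gaps) or len(overlaps):
        raise ConfigError(
            f"ID ranges must partition 1..{n}: "
            f"gaps at {gaps[:10].tolist()}, overlaps at {overlaps[:10].tolist()}"
        )

    cell_class = np.empty(n + 1, dtype=object)
    broad = np.empty(n + 1, dtype=object)
    for name, spans in base.items():
        for lo, hi in spans:
            cell_class[lo : hi + 1] = name
            broad[lo : hi + 1] = name
    for name, spans in ranges.items():
        if name not in NESTED_CLASSES:
            continue
        parent = NESTED_CLASSES[name]
        for lo, hi in spans:
            if not np.all(broad[lo : hi + 1] == parent):
                raise ConfigError(
                    f"{name} range ({lo},{hi}) must nest inside {parent}"
                )
            cell_class[lo : hi + 1] = name

    table = pd.DataFrame(
        {
            "id": np.arange(1, n + 1, dtype=np.int64),
            "cell_class": cell_class[1:],
            "broad_class": broad[1:],
            "subtype": cell_class[1:],
            "x": np.nan,
            "y": np.nan,
            "z": np.nan,
        }
    )
    if soma_path is not None:
        soma_df = pd.read_csv(soma_path)
    if soma_df is not None:
        soma = soma_df.set_index("id")
        for col in ("x", "y", "z"):
            if col in soma.columns:
                table[col] = table["id"].map(soma[col])
        if "subtype" in soma.columns:
            sub = table["id"].map(soma["subtype"])
            table["subtype"] = sub.fillna(table["subtype"])
    return CellCatalog(table=table)
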