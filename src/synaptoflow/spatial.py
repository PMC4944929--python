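"""Sample-edge artifacts and module mosaic geometry in the retinal plane.

An excised tissue sample loses every link that crossed the cut, so neurons
near the boundary look less connected than they are.  ``classify_edge_core``
splits neurons into an edge zone (soma within ``margin`` of any of the four
in-plane boundaries) and a core, and ``edge_effect_report`` compares mean
weighted degree and betweenness between the zones to quantify the artifact.

``module_geometry`` measures how module members (typically cone bipolar
cells) tile the retinal plane: each module's 2-D convex hull, its area and
centroid, all pairwise hull overlaps, and a tiling score (total pairwise
overlap area over total hull area — near 0 for a clean mosaic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Polygon

from .ingest import CellCatalog, ConfigError
from .metrics import NodeMetrics

__all__ = [
    "CoreEdgeLabels",
    "ModuleGeometry",
    "classify_edge_core",
    "edge_effect_report",
    "module_geometry",
]


@dataclass
class CoreEdgeLabels:
    """Per-neuron zone labels (core / edge / unknown)."""

    table: pd.DataFrame          # columns: id, zone
    margin: float
    plane_bounds: tuple
    plane_axes: tuple

    def ids_in_zone(self, zone: str) -> np.ndarray:
        return self.table.loc[self.table["zone"] == zone, "id"].to_numpy()


@dataclass
class ZoneReport:
    """Mean metrics per zone with core-vs-edge relative differences (%)."""

    table: pd.DataFrame          # rows core/edge/all: n, mean_k, mean_nBC
    n_excluded: int = 0          # neurons without coordinates

    def _mean(self, zone: str, col: str) -> float:
        row = self.table[self.table["zone"] == zone]
        return float(row[col].iloc[0]) if len(row) else np.nan

    @property
    def degree_deficit_pct(self) -> float:
        """(core − edge)/core mean weighted degree, in percent."""
        core, edge = self._mean("core", "mean_k"), self._mean("edge", "mean_k")
        return 100.0 * (core - edge) / core

    @property
    def nbc_deficit_pct(self) -> float:
        core, edge = self._mean("core", "mean_nBC"), self._mean("edge", "mean_nBC")
        return 100.0 * (core - edge) / core


@dataclass
class ModuleGeometry:
    """Convex-hull geometry of module member somata in the plane."""

    modules: pd.DataFrame        # module, n_members, hull_area, centroid_x/y, degenerate
    hulls: dict                  # module -> shapely Polygon (or None if degenerate)
    overlaps: pd.DataFrame       # module_a, module_b, overlap_area
    cell_class: str | None = None

    @property
    def tiling_score(self) -> float:
        """Total pairwise overlap area / total hull area; ~0 for a mosaic."""
        total_hull = self.modules["hull_area"].sum()
        if total_hull == 0:
            return np.nan
        return float(self.overlaps["overlap_area"].sum() / total_hull)


def classify_edge_core(
    catalog: CellCatalog,
    margin: float = 10.0,
    plane_bounds: tuple = (80.0, 114.0),
    plane_axes: tuple = ("x", "y"),
) -> CoreEdgeLabels:
    """Label neurons edge/core by lateral soma position.

    A neuron is ``edge`` iff either in-plane coordinate lies within
    ``margin`` of one of the four boundaries (0 or the plane extent);
    neurons without coordinates are ``unknown``.
    """
    lx, ly = plane_bounds
    if margin >= min(lx, ly) / 2:
        raise ConfigError(
            f"margin {margin} must be below half the smallest plane extent "
            f"({min(lx, ly) / 2})"
        )
    coords = catalog.table[list(plane_axes)].to_numpy(dtype=float)
    u, v = coords[:, 0], coords[:, 1]
    known = ~np.isnan(u) & ~np.isnan(v)
    near_edge = (
        (u <= margin) | (u >= lx - margin) | (v <= margin) | (v >= ly - margin)
    )
    zone = np.where(known, np.where(near_edge, "edge", "core"), "unknown")
    return CoreEdgeLabels(
        table=pd.DataFrame({"id": catalog.ids, "zone": zone}),
        margin=margin,
        plane_bounds=tuple(plane_bounds),
        plane_axes=tuple(plane_axes),
    )


def edge_effect_report(
    metrics: NodeMetrics, labels: CoreEdgeLabels
) -> ZoneReport:
    """Zone means of weighted degree (and nBC when present)."""
    zone = labels.table.set_index("id")["zone"]
    df = metrics.to_frame().rename(columns={"node": "id"})
    df["zone"] = df["id"].map(zone)
    known = df[df["zone"].isin(["core", "edge"])]
    rows = []
    for name, grp in [
        ("core", known[known["zone"] == "core"]),
        ("edge", known[known["zone"] == "edge"]),
        ("all", known),
    ]:
        if len(grp) == 0:
            continue
        row = {"zone": name, "n": len(grp), "mean_k": grp["k"].mean()}
        if "nBC" in grp.columns:
            row["mean_nBC"] = grp["nBC"].mean()
        rows.append(row)
    return ZoneReport(
        table=pd.DataFrame(rows),
        n_excluded=int((df["zone"] == "unknown").sum() + df["zone"].isna().sum()),
    )


def module_geometry(
    catalog: CellCatalog,
    partition,
    cell_class: str | None = None,
    plane_axes: tuple = ("x", "y"),
    min_members: int = 3,
) -> ModuleGeometry:
    """Per-module convex hulls, centroids and pairwise overlaps in the plane.

    Restricted to ``cell_class`` members when given.  Modules with fewer than
    ``min_members`` located members (or collinear members) are recorded as
    degenerate with zero hull area and excluded from overlaps.
    """
    tab = catalog.table
    if cell_class is not None:
        tab = tab[tab["cell_class"] == cell_class]
    tab = tab.dropna(subset=list(plane_axes))
    labels = partition.labels_for(tab["id"].to_numpy())

    rows, hulls = [], {}
    for m in np.unique(labels):
        pts = tab.loc[labels == m, list(plane_axes)].to_numpy(dtype=float)
        hull = None
        area, cx, cy = 0.0, np.nan, np.nan
        degenerate = True
        if len(pts) >= min_members:
            geom = MultiPoint([tuple(p) for p in pts]).convex_hull
            if isinstance(geom, Polygon) and geom.area > 0:
                hull = geom
                area = float(geom.area)
                cx, cy = geom.centroid.x, geom.centroid.y
                degenerate = False
        if degenerate and len(pts):
            cx, cy = pts.mean(axis=0)
        rows.append(
            {
                "module": int(m),
                "n_members": int((labels == m).sum()),
                "hull_area": area,
                "centroid_u": float(cx),
                "centroid_v": float(cy),
                "degenerate": degenerate,
            }
        )
        hulls[int(m)] = hull

    ov_rows = []
    mods = [m for m, h in hulls.items() if h is not None]
    for i, a in enumerate(mods):
        for b in mods[i + 1 :]:
            inter = hulls[a].intersection(hulls[b])
            ov_rows.append(
                {"module_a": a, "module_b": b, "overlap_area": float(inter.area)}
            )
    return ModuleGeometry(
        modules=pd.DataFrame(rows),
        hulls=hulls,
        overlaps=pd.DataFrame(ov_rows,
                              columns=["module_a", "module_b", "overlap_area"]),
        cell_class=cell_class,
    )
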