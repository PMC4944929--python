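"""Focus-neuron circuit reports and cross-measure node rankings.

For a focus neuron the adjacency row is split by partner cell class:
*strong* partners (weight above ``strong_min``, default 10) sorted by weight,
candidate *feedback* partners — bipolar cells reached by weak links (weight
at most ``feedback_max``, default 2, the band expected of gain-control
return signals) — and tallies of Off- versus On-type cone-bipolar inputs.
The Off/On assignment of cone-bipolar subtypes is configuration, defaulting
to the standard inner-plexiform convention (types 1–4 Off; 5 and above,
including XBC, On).  No claim about synaptic direction is made; links are
undirected and "input"/"feedback" labels follow the weight-band convention.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .communities import FlowSummary
from .ingest import CellCatalog, WeightedGraph
from .metrics import NodeMetrics

__all__ = [
    "CircuitReport",
    "DEFAULT_OFF_ON_MAP",
    "circuit_report",
    "rank_nodes",
]

#: Off/On response type per cone-bipolar subtype suffix.
DEFAULT_OFF_ON_MAP = {
    "1": "Off", "2": "Off", "3A": "Off", "3B": "Off", "4": "Off",
    "5": "On", "5A": "On", "5R": "On", "5X": "On",
    "6": "On", "7": "On", "8": "On", "9": "On", "XBC": "On",
}

_AC_CLASSES = {"NFac", "WFac", "OffSAC", "OnSAC"}


@dataclass
class CircuitReport:
    """Strong/feedback link lists and class tallies for one focus neuron."""

    focus: int
    focus_class: str
    focus_subtype: str
    strong: pd.DataFrame         # partner, cell_class, subtype, weight (desc)
    feedback: pd.DataFrame       # weak bipolar partners
    tallies: dict
    strong_min: float
    feedback_max: float

    @property
    def strongest_weight(self) -> float:
        return float(self.strong["weight"].iloc[0]) if len(self.strong) else 0.0

    def to_dict(self) -> dict:
        return {
            "focus": self.focus,
            "focus_class": self.focus_class,
            "focus_subtype": self.focus_subtype,
            "strong_min": self.strong_min,
            "feedback_max": self.feedback_max,
            "strong_links": self.strong.to_dict(orient="records"),
            "feedback_links": self.feedback.to_dict(orient="records"),
            "tallies": self.tallies,
        }

    def to_json(self, path=None, **kwargs) -> str | None:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    def to_text(self) -> str:
        lines = [
            f"Circuit report for neuron #{self.focus} "
            f"({self.focus_class}, {self.focus_subtype})",
            f"  strong links (weight > {self.strong_min:g}): "
            f"{len(self.strong)}",
        ]
        for _, r in self.strong.iterrows():
            lines.append(
                f"    -> #{int(r['partner'])} ({r['cell_class']}, "
                f"{r['subtype']}): weight {round(r['weight'])} "
                f"({r['weight']:.3f})"
            )
        lines.append(
            f"  feedback candidates (BC links, weight <= "
            f"{self.feedback_max:g}): {len(self.feedback)}"
        )
        lines.append(f"  tallies: {self.tallies}")
        return "\n".join(lines)


def _cbc_response(subtype: str, off_on_map: dict) -> str | None:
    # subtype strings look like "cBC-3A", "cBC5R", "XBC" ...
    s = str(subtype)
    if "XBC" in s.upper():
        key = "XBC"
    else:
        m = re.search(r"(\d[A-Za-z]?)\s*$", s)
        key = m.group(1).upper() if m else s
    return off_on_map.get(key)


def circuit_report(
    graph: WeightedGraph,
    catalog: CellCatalog,
    focus: int,
    strong_min: float = 10.0,
    feedback_max: float = 2.0,
    off_on_map: dict | None = None,
) -> CircuitReport:
    """Partition the focus neuron's adjacency row into a circuit report."""
    off_on_map = dict(DEFAULT_OFF_ON_MAP if off_on_map is None else off_on_map)
    fi = graph.index_of(focus)
    row = graph.weights[fi]
    partners = graph.node_ids[row > 0]
    weights = row[row > 0]
    info = pd.DataFrame(
        {
            "partner": partners,
            "cell_class": [catalog.class_of(v) for v in partners],
            "subtype": [catalog.subtype_of(v) for v in partners],
            "weight": weights,
        }
    )
    strong = (
        info[info["weight"] > strong_min]
        .sort_values(["weight", "partner"], ascending=[False, True])
        .reset_index(drop=True)
    )
    feedback = (
        info[
            info["cell_class"].isin(["cBC", "rBC"])
            & (info["weight"] <= feedback_max)
        ]
        .sort_values(["weight", "partner"], ascending=[False, True])
        .reset_index(drop=True)
    )

    cbc = info[info["cell_class"] == "cBC"]
    off = on = unclassified = 0
    for _, r in cbc.iterrows():
        resp = _cbc_response(r["subtype"], off_on_map)
        if resp == "Off":
            off += 1
        elif resp == "On":
            on += 1
        else:
            warnings.warn(
                f"cBC subtype {r['subtype']!r} has no Off/On mapping"
            )
            unclassified += 1
    tallies = {
        "off_cbc": off,
        "on_cbc": on,
        "unclassified_cbc": unclassified,
        "rbc": int((info["cell_class"] == "rBC").sum()),
        "ac": int(info["cell_class"].isin(_AC_CLASSES).sum()),
        "gc": int((info["cell_class"] == "GC").sum()),
    }
    return CircuitReport(
        focus=int(focus),
        focus_class=catalog.class_of(focus),
        focus_subtype=catalog.subtype_of(focus),
        strong=strong,
        feedback=feedback,
        tallies=tallies,
        strong_min=strong_min,
        feedback_max=feedback_max,
    )


@dataclass
class RankTable:
    """Side-by-side top-k node IDs under flow, betweenness and strength."""

    table: pd.DataFrame          # rank, by_flow, by_nbc, by_strength
    overlaps: dict               # pairwise and three-way intersection sizes

    def top(self, measure: str) -> list:
        return self.table[f"by_{measure}"].tolist()


def _top_ids(node_ids: np.ndarray, values: np.ndarray, k: int) -> np.ndarray:
    order = np.lexsort((node_ids, -values))   # value desc, ties by smaller ID
    return node_ids[order[:k]]


def rank_nodes(
    flow: FlowSummary, metrics: NodeMetrics, top_k: int = 10
) -> RankTable:
    """Compare node rankings by signal flow, nBC and weighted degree."""
    if sorted(flow.node_ids.tolist()) != sorted(metrics.node_ids.tolist()):
        raise ValueError("flow and metrics cover different node sets")
    if metrics.nbc is None:
        raise ValueError("metrics must include betweenness (nbc)")
    order = np.argsort(metrics.node_ids)
    ids = metrics.node_ids[order]
    flow_order = np.argsort(flow.node_ids)
    p = flow.p[flow_order]

    by_flow = _top_ids(ids, p, top_k)
    by_nbc = _top_ids(ids, metrics.nbc[order], top_k)
    by_k = _top_ids(ids, metrics.strength[order], top_k)
    table = pd.DataFrame(
        {
            "rank": np.arange(1, top_k + 1),
            "by_flow": by_flow,
            "by_nbc": by_nbc,
            "by_strength": by_k,
        }
    )
    sets = {"flow": set(by_flow), "nbc": set(by_nbc), "strength": set(by_k)}
    overlaps = {
        "flow_nbc": len(sets["flow"] & sets["nbc"]),
        "flow_strength": len(sets["flow"] & sets["strength"]),
        "nbc_strength": len(sets["nbc"] & sets["strength"]),
        "all_three": len(sets["flow"] & sets["nbc"] & sets["strength"]),
    }
    return RankTable(table=table, overlaps=overlaps)
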