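"""Synthetic retina-like contact samples with known ground truth.

The generator emulates the structure of raw EM contact lists so every
pipeline stage can be exercised against a known answer: typed neurons placed
uniformly in a 3-D sample box, spatially planted modules (membership by
nearest planted center in the retinal plane), a Poisson number of contacts
per cell pair whose rate decays exponentially with lateral soma distance and
is boosted within modules, lognormal contact areas with a heavy right tail
(calibrated so ≈41% of contacts survive a 0.08 μm² area filter), a
configurable fraction of contacts double-listed in both i→j and j→i order,
glia contacts to be dropped at ingest, and boundary truncation of contacts
jittered outside the box.

``truncation_experiment`` additionally surrounds the box with a collar of
tissue at the same density and returns the same link draw with and without
the collar, so the degree deficit induced by sample excision can be measured
against a known complete network.

What this generator does *not* emulate: neurite morphology (contacts hang
off soma-to-soma geometry, not dendritic arbors), depth stratification of
the plexiform sublaminae, and class-specific connectivity rules.  Recovery
results on these samples show the pipeline's correctness, not that real
retina modules are equally easy to find.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .communities import Partition
from .ingest import CellCatalog, ContactTable, load_cell_catalog

__all__ = [
    "GeneratorParams",
    "SyntheticSample",
    "TruncationExperiment",
    "DEFAULT_CLASS_COUNTS",
    "generate_sample",
    "truncation_experiment",
    "edge_core_degree_deficit",
    "write_sample",
]

#: Default class counts mirroring the 950-neuron retina sample (the plain
#: WFac count excludes the nested starburst blocks: 135 + 15 + 13 = 163).
DEFAULT_CLASS_COUNTS = {
    "GC": 36,
    "NFac": 190,
    "WFac": 135,
    "OffSAC": 15,
    "OnSAC": 13,
    "cBC": 307,
    "rBC": 144,
    "other": 110,
}

_CBC_SUBTYPES = [
    "cBC-1", "cBC-2", "cBC-3A", "cBC-3B", "cBC-4", "cBC-5A", "cBC-5R",
    "cBC-6", "cBC-7", "cBC-8", "cBC-9", "XBC",
]


@dataclass(frozen=True)
class GeneratorParams:
    """Study conditions for the synthetic sample.

    ``base_rate`` is the Poisson mean number of contacts for a
    between-module pair at zero lateral distance; the rate decays as
    exp(−d/``decay_scale``) with lateral soma distance d and is multiplied
    by ``rate_ratio`` within a planted module.  Areas are lognormal on μm²;
    the default location parameter puts ≈41% of contact areas at or above
    0.08 μm².  ``duplicate_fraction`` is the per-contact probability of a
    second, reversed listing.
    """

    box: tuple = (132.0, 114.0, 80.0)
    class_counts: tuple = tuple(sorted(DEFAULT_CLASS_COUNTS.items()))
    n_glia: int = 173
    n_modules: int = 6
    module_centers: tuple | None = None
    base_rate: float = 1.2
    decay_scale: float = 10.5         # μm
    rate_ratio: float = 6.0
    glia_rate_factor: float = 0.25
    area_log_mu: float = -2.7533      # ln μm²; P(area >= 0.08) ≈ 0.41
    area_log_sigma: float = 1.0
    duplicate_fraction: float = 0.14
    contact_jitter: float = 1.5       # μm, isotropic contact-centroid noise

    def __post_init__(self):
        counts = dict(self.class_counts)
        if any(v < 0 for v in counts.values()):
            raise ValueError("class counts must be nonnegative")
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")
        if self.decay_scale <= 0:
            raise ValueError("decay_scale must be > 0")
        if self.rate_ratio < 1:
            raise ValueError("rate_ratio must be >= 1")
        if not (0 <= self.duplicate_fraction <= 1):
            raise ValueError("duplicate_fraction must lie in [0, 1]")

    @property
    def counts(self) -> dict:
        return dict(self.class_counts)

    @property
    def n_neurons(self) -> int:
        return sum(self.counts.values())

    def centers(self) -> np.ndarray:
        """Planted module centers in the retinal plane (grid by default)."""
        if self.module_centers is not None:
            return np.asarray(self.module_centers, dtype=float)
        lx, ly, _ = self.box
        m = self.n_modules
        nx = int(np.ceil(np.sqrt(m)))
        ny = int(np.ceil(m / nx))
        pts = [
            ((i + 0.5) / nx * lx, (j + 0.5) / ny * ly)
            for j in range(ny)
            for i in range(nx)
        ]
        return np.array(pts[:m])


@dataclass
class SyntheticSample:
    """A generated contact table with its ground truth."""

    contacts: ContactTable
    catalog: CellCatalog
    truth: Partition
    truncated: pd.DataFrame           # boundary-lost contacts
    pair_ledger: pd.DataFrame         # lo, hi, n_contacts, total_area (emitted)
    params: GeneratorParams
    seed: int


def _ranges_from_counts(counts: dict) -> dict:
    """Sequential ID ranges; starburst blocks lead the wide-field span."""
    ranges = {}
    nxt = 1

    def span(n):
        nonlocal nxt
        lo, hi = nxt, nxt + n - 1
        nxt += n
        return (lo, hi)

    ranges["GC"] = [span(counts["GC"])]
    ranges["NFac"] = [span(counts["NFac"])]
    wf_lo = nxt
    off = span(counts["OffSAC"])
    on = span(counts["OnSAC"])
    span(counts["WFac"])
    ranges["WFac"] = [(wf_lo, nxt - 1)]
    ranges["OffSAC"] = [off]
    ranges["OnSAC"] = [on]
    ranges["cBC"] = [span(counts["cBC"])]
    ranges["rBC"] = [span(counts["rBC"])]
    ranges["other"] = [span(counts["other"])]
    return ranges


def _build_catalog(params: GeneratorParams, positions: np.ndarray,
                   rng) -> CellCatalog:
    ranges = _ranges_from_counts(params.counts)
    n = params.n_neurons
    soma = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "x": positions[:, 0],
            "y": positions[:, 1],
            "z": positions[:, 2],
        }
    )
    catalog = load_cell_catalog(ranges=ranges, soma_df=soma)
    cbc_mask = catalog.table["cell_class"] == "cBC"
    catalog.table.loc[cbc_mask, "subtype"] = rng.choice(
        _CBC_SUBTYPES, size=int(cbc_mask.sum())
    )
    return CellCatalog(table=catalog.table)


def _nearest_center(positions: np.ndarray, centers: np.ndarray) -> np.ndarray:
    d2 = ((positions[:, None, :2] - centers[None, :, :]) ** 2).sum(-1)
    return d2.argmin(axis=1) + 1


def _draw_pair_contacts(pos, labels, params, rng):
    """Poisson contact counts for all unordered pairs; returns (i_idx, j_idx)."""
    n = len(pos)
    iu, ju = np.triu_indices(n, k=1)
    d = np.sqrt(((pos[iu, :2] - pos[ju, :2]) ** 2).sum(-1))
    rate = params.base_rate * np.exp(-d / params.decay_scale)
    same = labels[iu] == labels[ju]
    rate = rate * np.where(same, params.rate_ratio, 1.0)
    counts = rng.poisson(rate)
    nz = counts > 0
    return np.repeat(iu[nz], counts[nz]), np.repeat(ju[nz], counts[nz])


def generate_sample(params: GeneratorParams | None = None,
                    seed: int = 0) -> SyntheticSample:
    """Generate one synthetic contact sample; bit-reproducible from (params, seed)."""
    if params is None:
        params = GeneratorParams()
    rng = np.random.default_rng(seed)
    lx, ly, lz = params.box
    n = params.n_neurons

    pos = rng.uniform([0, 0, 0], [lx, ly, lz], size=(n, 3))
    catalog = _build_catalog(params, pos, rng)
    centers = params.centers()
    labels = _nearest_center(pos, centers)
    truth = Partition(
        node_ids=np.arange(1, n + 1), labels=labels, method="planted",
        seed=seed,
    )

    ii, jj = _draw_pair_contacts(pos, labels, params, rng)
    n_contacts = len(ii)
    areas = rng.lognormal(params.area_log_mu, params.area_log_sigma,
                          n_contacts)
    mid = (pos[ii] + pos[jj]) / 2.0
    centroids = mid + rng.normal(0.0, params.contact_jitter, (n_contacts, 3))

    rows = pd.DataFrame(
        {
            "cell_i": ii + 1,
            "cell_j": jj + 1,
            "area": areas,
            "x": centroids[:, 0],
            "y": centroids[:, 1],
            "z": centroids[:, 2],
        }
    )
    inside = (
        (centroids >= 0).all(axis=1)
        & (centroids[:, 0] <= lx)
        & (centroids[:, 1] <= ly)
        & (centroids[:, 2] <= lz)
    )
    truncated = rows[~inside].reset_index(drop=True)
    rows = rows[inside]

    # glia contacts, to be dropped at the catalog stage
    if params.n_glia > 0:
        gpos = rng.uniform([0, 0, 0], [lx, ly, lz], size=(params.n_glia, 3))
        d = np.sqrt(
            ((gpos[:, None, :2] - pos[None, :, :2]) ** 2).sum(-1)
        ).ravel()
        rate = (
            params.base_rate
            * params.glia_rate_factor
            * np.exp(-d / params.decay_scale)
        )
        counts = rng.poisson(rate)
        nz = counts > 0
        gi, nj = np.divmod(np.flatnonzero(nz), n)
        reps = counts[nz]
        gi = np.repeat(gi, reps)
        nj = np.repeat(nj, reps)
        g_areas = rng.lognormal(params.area_log_mu, params.area_log_sigma,
                                len(gi))
        g_mid = (gpos[gi] + pos[nj]) / 2.0
        g_rows = pd.DataFrame(
            {
                "cell_i": n + 1 + gi,
                "cell_j": nj + 1,
                "area": g_areas,
                "x": g_mid[:, 0],
                "y": g_mid[:, 1],
                "z": g_mid[:, 2],
            }
        )
        rows = pd.concat([rows, g_rows], ignore_index=True)

    # ledger of emitted neuron-neuron pair totals (before double listing)
    nn = rows[rows["cell_i"] <= n]
    ledger = (
        pd.DataFrame(
            {
                "lo": np.minimum(nn["cell_i"], nn["cell_j"]),
                "hi": np.maximum(nn["cell_i"], nn["cell_j"]),
                "area": nn["area"],
            }
        )
        .groupby(["lo", "hi"])
        .agg(n_contacts=("area", "size"), total_area=("area", "sum"))
        .reset_index()
    )

    dup_mask = rng.random(len(rows)) < params.duplicate_fraction
    dups = rows[dup_mask].rename(
        columns={"cell_i": "cell_j", "cell_j": "cell_i"}
    )[["cell_i", "cell_j", "area", "x", "y", "z"]]
    rows = pd.concat([rows, dups], ignore_index=True)
    rows = rows.iloc[rng.permutation(len(rows))].reset_index(drop=True)

    contacts = ContactTable(
        records=rows,
        provenance=[
            f"synthetic sample (seed={seed}, {n} neurons, "
            f"{params.n_glia} glia, {len(rows)} listed contacts)"
        ],
    )
    return SyntheticSample(
        contacts=contacts,
        catalog=catalog,
        truth=truth,
        truncated=truncated,
        pair_ledger=ledger,
        params=params,
        seed=seed,
    )


@dataclass
class TruncationExperiment:
    """Paired full / excised contact draws over one neuron placement."""

    full_contacts: ContactTable
    truncated_contacts: ContactTable
    catalog: CellCatalog              # box neurons only, with coordinates
    n_collar: int
    margin: float
    params: GeneratorParams
    seed: int


def truncation_experiment(
    params: GeneratorParams | None = None,
    margin: float = 10.0,
    seed: int = 0,
) -> TruncationExperiment:
    """One link draw over the box plus a density-matched collar of width
    ``margin``; the truncated variant drops collar neurons and every link
    touching them, emulating sample excision.

    Glia, double listings and centroid jitter are disabled here so the
    excision effect is measured on a clean network.
    """
    if params is None:
        params = GeneratorParams()
    lx, ly, lz = params.box
    if margin < 0 or (margin and margin >= min(lx, ly) / 2):
        raise ValueError("margin must be >= 0 and below half the plane extent")
    rng = np.random.default_rng(seed)
    n = params.n_neurons

    pos = rng.uniform([0, 0, 0], [lx, ly, lz], size=(n, 3))
    catalog = _build_catalog(params, pos, rng)

    # collar strips at matching areal density: left, right, bottom, top
    strips = [
        ((-margin, 0.0), (-margin, ly + margin)),
        ((lx, lx + margin), (-margin, ly + margin)),
        ((0.0, lx), (-margin, 0.0)),
        ((0.0, lx), (ly, ly + margin)),
    ]
    areas = np.array(
        [(x1 - x0) * (y1 - y0) for (x0, x1), (y0, y1) in strips]
    )
    density = n / (lx * ly)
    n_collar = int(round(density * areas.sum()))
    cpos = np.zeros((n_collar, 3))
    if n_collar:
        which = rng.choice(4, size=n_collar, p=areas / areas.sum())
        for s, ((x0, x1), (y0, y1)) in enumerate(strips):
            m = which == s
            cpos[m, 0] = rng.uniform(x0, x1, m.sum())
            cpos[m, 1] = rng.uniform(y0, y1, m.sum())
        cpos[:, 2] = rng.uniform(0, lz, n_collar)

    all_pos = np.vstack([pos, cpos])
    labels = _nearest_center(all_pos, params.centers())
    ii, jj = _draw_pair_contacts(all_pos, labels, params, rng)
    areas_c = rng.lognormal(params.area_log_mu, params.area_log_sigma, len(ii))
    mid = (all_pos[ii] + all_pos[jj]) / 2.0
    rows = pd.DataFrame(
        {
            "cell_i": ii + 1,
            "cell_j": jj + 1,
            "area": areas_c,
            "x": mid[:, 0],
            "y": mid[:, 1],
            "z": mid[:, 2],
        }
    )
    inner = rows[(rows["cell_i"] <= n) & (rows["cell_j"] <= n)]
    note = f"truncation experiment seed={seed} margin={margin}"
    return TruncationExperiment(
        full_contacts=ContactTable(records=rows.reset_index(drop=True),
                                   provenance=[note + " (full)"]),
        truncated_contacts=ContactTable(records=inner.reset_index(drop=True),
                                        provenance=[note + " (excised)"]),
        catalog=catalog,
        n_collar=n_collar,
        margin=margin,
        params=params,
        seed=seed,
    )


def edge_core_degree_deficit(
    experiment: TruncationExperiment,
    threshold: float = 0.16,
    zone_margin: float = 10.0,
) -> float:
    """Edge-vs-core mean weighted-degree deficit (%) in the excised sample."""
    from .ingest import aggregate_links, filter_contacts
    from .metrics import weighted_degree
    from .spatial import classify_edge_core, edge_effect_report

    table = filter_contacts(experiment.truncated_contacts, threshold)
    graph = aggregate_links(
        table, threshold, node_ids=experiment.catalog.ids
    )
    nm = weighted_degree(graph)
    lx, ly, _ = experiment.params.box
    labels = classify_edge_core(
        experiment.catalog, margin=zone_margin, plane_bounds=(lx, ly)
    )
    return edge_effect_report(nm, labels).degree_deficit_pct


def write_sample(sample: SyntheticSample, outdir) -> dict:
    """Write contacts.csv, cells.csv and truth_membership.txt to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "contacts": outdir / "contacts.csv",
        "cells": outdir / "cells.csv",
        "membership": outdir / "truth_membership.txt",
    }
    sample.contacts.records.to_csv(paths["contacts"], index=False)
    sample.catalog.table.to_csv(paths["cells"], index=False)
    with open(paths["membership"], "w") as fh:
        for v, l in zip(sample.truth.node_ids, sample.truth.labels):
            fh.write(f"{v} {l}\n")
    return paths
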