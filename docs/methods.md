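# Methods

## From contact areas to a weighted graph

The input is a list of cell-to-cell membrane contacts: (cell_i, cell_j,
area in μm², x, y, z in μm).  Contact area is a proxy for synapse presence —
empirically, a 0.08 μm² contact has roughly even odds of hosting a synapse —
so graph construction is threshold-driven:

1. **Row hygiene.** Self-contacts are dropped and counted; rows with
   non-numeric required fields are dropped and reported by file line number.
2. **Double-listing correction.** The same physical contact can be listed
   both as i→j and j→i (about 14% of rows in data of this kind).  Rows
   identical in (unordered pair, area, x, y, z) are collapsed to one.
   Distinct contacts between the same pair always survive, whatever their
   listing order.  This makes aggregation exactly invariant to the
   duplication rate, which the synthetic twin test verifies.
3. **Filtering and aggregation.** Under the default `per_contact` mode,
   individual contacts below the area threshold θ (default 0.16 μm²) are
   removed, and survivors are summed per unordered pair, so every retained
   link has weight ≥ 1.  The alternative `per_pair_total` mode sums all
   contacts ≥ 0.08 μm² and keeps pairs whose *total* reaches θ; it yields a
   superset of the per-contact link set and exists because either reading of
   a two-stage threshold protocol is defensible.  Thresholds are inclusive
   (area ≥ θ retained): θ marks the 50% synapse-probability point, so
   boundary contacts belong in.  A strict-inequality flag exists.
4. **Weights.** A(i,j) = (summed area)/θ, stored at full precision; reports
   round for display.  The matrix is symmetric with zero diagonal; no
   direction is inferred because none is observed.

Glia are catalogued out: contacts touching IDs absent from the neuron
catalog are dropped with a logged count before aggregation.

## Centrality conventions

Betweenness uses unnormalized, unordered-pair counting with endpoints
excluded for node betweenness; tied geodesics split credit fractionally.
On the weighted network a link of weight w has length 1/w, so strong
synaptic links are short.  This inverse-weight rule is a convention, not an
observation; ranked outputs are therefore the stable quantity, not raw
betweenness values.  The geodesic census uses unweighted hop counts over
ordered pairs, with disconnected pairs tallied separately.

## The map equation

Visit rates of the stationary undirected weighted walk are
p_i = k_i / Σ_j k_j; no teleportation is needed because the undirected
chain is already ergodic on each component, and nodes without links get
p_i = 0 and singleton modules.  A two-level partition M costs

    L(M) = q↷ H(Q) + Σ_m (p_m∘ + q_m) H(P_m)        [bits],

where q_m = (boundary link weight of module m)/(total strength),
q↷ = Σ_m q_m, p_m∘ = Σ_{i∈m} p_i, H(Q) is the entropy of {q_m/q↷} and
H(P_m) the entropy of {q_m, p_i∈m} normalized by (p_m∘ + q_m).  All logs
are base 2; a single-module partition costs exactly −Σ p_i log2 p_i.
Only the flat two-level code is implemented — no hierarchical variant, no
overlapping modules.

**Search.** Greedy node moves (each node may join a neighbouring module or
split off alone) followed by module aggregation into supernodes, repeated
until no move helps; `trials` restarts with seeded shuffled visit orders,
lowest codelength wins, earliest trial on ties.  Results are reproducible
bit-for-bit given (graph, seed, trials).  On 8-node graphs the greedy
optimum coincides with the exhaustive minimum over all set partitions in
≥95% of random instances (tested); greedy search carries no global
optimality guarantee beyond that.

Modules are relabeled 1..K by total flow descending, ties broken by
smallest member ID.  "Non-trivial module" means >15 members or >1% of total
flow.  Structural baselines: Newman-Girvan divisive (cut max edge
betweenness, recompute), greedy modularity agglomeration, and k-means on
spectral bases — the k−1 nontrivial Laplacian eigenvectors, or the leading
positive-eigenvalue eigenvectors of the modularity matrix — with 20 seeded
k-means restarts and a Q-scan over k = 2..20.

## Spatial analysis

Edge/core zoning is purely lateral: a neuron is *edge* if either in-plane
soma coordinate lies within `margin` (default 10 μm) of the four plane
boundaries.  The analysis plane and its bounds are configuration (default
80×114 μm), never hard-coded, because the lateral axes of an EM volume are
a choice of frame.  Neurons without coordinates are excluded from zone
means and logged.

Module mosaic geometry takes one cell class (typically cone bipolars),
builds each module's 2-D convex hull, and reports areas, centroids,
pairwise hull intersections and a **tiling score** = total pairwise overlap
area / total hull area.  The score is this package's operationalization of
"tiled mosaic" — near 0 means near-disjoint hulls; no standard formula
exists.  Modules with fewer than three located members are flagged
degenerate and excluded from overlaps.

## Layout

The spectral distance embedding is classical MDS on geodesic hop counts:
double-center −½D², keep the top eigenpairs with positive eigenvalues,
scale eigenvectors by √eigenvalue.  Residual stress Σ(‖x_i−x_j‖ − D_ij)² is
reported for audit; it is zero (to 1e-8) exactly when D is Euclidean-
realizable.  Note that gradient-based stress minimizers (SMACOF) optimize
stress directly and reach lower stress on non-Euclidean D — the spectral
solution trades that for determinism, speed and a closed form.  Eigenvector
signs are fixed by making each axis's largest-magnitude coordinate
positive; nodes outside the largest component are placed on a display ring
at 1.2× the embedding radius and flagged.  Hop distances (not inverse-
weight lengths) feed the layout, keeping the picture a topology sketch.

## Circuit reports

For a focus neuron the adjacency row is split into strong partners
(weight > 10 by default) and feedback candidates — bipolar partners with
weight ≤ 2, the band plausible for gain-control return signals.  Off/On
tallies of cone-bipolar inputs come from a subtype→response map that is
configuration, defaulting to the standard inner-plexiform convention
(types 1–4 Off; 5A/5R/5X, 6–9 and XBC On).  No synaptic direction or sign
is claimed anywhere.

## The synthetic generator

Defaults are the study conditions; each was chosen once and frozen:

| parameter | default | rationale |
|---|---|---|
| box | 132×114×80 μm | the EM sample volume |
| class counts | 36 GC, 190 NFac, 163 WFac (15 Off-/13 On-SAC), 307 cBC, 144 rBC, 110 other | the catalog ID ranges |
| glia | 173, rate factor 0.25 | present in raw data, removed at ingest |
| planted modules | 6, on a 3×2 plane grid | Voronoi cells of ~44×57 μm, a scale the flow decomposition resolves cleanly |
| base rate | 1.2 contacts/pair at d = 0 | gives ~10⁵ listed contacts and mean weighted degree ~65 at θ = 0.16 — a dense, retina-like graph that still runs in seconds |
| decay scale λ | 10.5 μm | short-range neurite contact scale; with the excision margin of 10 μm this reproduces the ~20–25% edge-zone degree deficit |
| within/between ratio ρ | 6 | strong enough for reliable recovery (ARI > 0.9 across seeds), weak enough that modules stay spatially, not trivially, separable |
| areas | lognormal, μ = ln 0.08 − 0.2275σ, σ = 1 | heavy right tail; puts 41% of contact areas at or above 0.08 μm², matching the reported survival of the synapse-probability filter |
| duplicate fraction d | 0.14 | the reported over-counting rate; applied per contact, the simplest mechanism consistent with it |
| contact jitter | 1.5 μm | displaces contact centroids off the soma midpoint; contacts jittered outside the box land on the truncated-links ledger |

Contacts per pair are Poisson with rate base_rate · exp(−d_lateral/λ) ·
(ρ if same planted module).  Everything is a pure function of
(params, seed).

**Truncation experiment.** The box is surrounded by a collar of width
`margin` populated at the same areal density; one link draw covers box and
collar, and the excised variant drops collar neurons with every incident
link.  Margin 0 means no collar and identical samples.  Duplicates, glia
and jitter are off here so the excision effect is measured cleanly.  One
consequence of this emulation: links longer than the collar are never
realized, so the edge-vs-core deficit *peaks* when λ is near the collar
width rather than growing without bound in λ (measured ≈17/23/20% at
λ = 5/10/20 μm).  The deficit at the default λ sits in the 20–25% band
reported for real excised samples.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: neurite morphology (contacts hang off
soma-to-soma geometry, not dendritic arbors, so contact positions are only
loosely tied to cell positions), depth stratification of the plexiform
sublaminae, class-specific connectivity rules (a cone bipolar here is as
likely to touch a ganglion cell as another bipolar at equal distance), and
the long-tailed spatial reach of horizontal-like "other" cells.  Recovery
of planted modules shows the pipeline finds structure that is present; it
says nothing about whether real retinal modules are as crisp.

## Numerical choices and degenerate inputs

- Codelength uses 0·log 0 = 0 throughout; moves are accepted only below a
  −1e-12 improvement threshold, so floating-point noise cannot cycle.
- Adjacency CSVs are written at 17 significant digits and parsed with a
  correctly-rounded float reader, so write-then-read round-trips bitwise.
  Read matrices are symmetrized after a 1e-9 symmetry check (asymmetric
  input is an error naming the worst entry).
- k-means uses 20 restarts with a fixed seed; spectral bases drop the
  trivial Laplacian eigenvector and non-positive modularity eigenvalues.
- All-zero graphs, empty contact tables, thresholds ≤ 0, margins beyond
  half the plane, unmapped cell classes and unknown node IDs raise typed
  errors naming the offender; unreachable divisive targets return the best
  achieved partition with a warning.
- Betweenness ties are resolved identically by implementation and test
  oracle only when path lengths are exact in floating point; the test
  suite therefore draws power-of-two weights for weighted instances.

## Problem sizes

Tests and the acceptance script run the full 950-neuron synthetic sample
(~10⁵ contacts): generation ~0.5 s, aggregation <0.1 s, a 10-trial flow
decomposition a few seconds.  Exhaustive oracles run at 8 nodes (4,140
partitions per graph) and ≤12 nodes (path enumeration), the scales at which
enumeration is exact and fast.  Recovery statistics use 10 generator seeds;
the excision experiment averages 6.
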