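# synaptoflow

Weighted-network analysis of cellular connectomes, built for electron-
microscopy contact data of the kind produced for the mouse retina inner
plexiform layer: a list of cell-to-cell membrane contacts, each with its
apposition area (μm²) and 3-D centroid, over a catalog of typed neurons
(ganglion cells, near/wide-field amacrines including the starburst
subclasses, cone and rod bipolar cells).

The package turns raw contacts into a symmetric weighted graph and asks
where the signal goes: which neurons carry the most random-walk flow, how
the network decomposes into modules, how those modules tile the retinal
plane, and how badly sample excision distorts it all.

## What it computes

**Graph construction.** Contacts are filtered by an area threshold (a 0.08
μm² contact has ~50% synapse probability; 0.16 μm² is the conservative
default), double listings of the same contact in i→j and j→i order are
collapsed, and per-pair areas are summed.  The link weight is the summed
contact area as a multiple of the threshold:

    A(i,j) = Σ contacts(i,j) area / θ,     A(i,j) = A(j,i),  A(i,i) = 0.

**Centrality and paths.** Weighted degree k_i = Σ_j A(i,j), node and edge
betweenness (Brandes accumulation, unordered pairs, fractional credit for
tied geodesics, link length 1/weight on the weighted network), and a census
of geodesic hop lengths over all ordered node pairs.

**Flow modules (map equation).** A random walker on the undirected weighted
graph visits node i with probability p_i = k_i / Σk.  A two-level partition
M is scored by its description length in bits,

    L(M) = q↷ H(Q) + Σ_m (p_m∘ + q_m) H(P_m),

with q_m the module exit probability, q↷ = Σ q_m, p_m∘ the within-module
visit rate, and H(·) Shannon entropies of the normalized exit and
within-module rate vectors.  A seeded greedy node-move/module-aggregation
search with restarts minimizes L.  Structural alternatives (Newman-Girvan
divisive, greedy modularity agglomeration, spectral clustering of the graph
Laplacian or modularity matrix, all scored by Newman's Q) and role metrics
(participation coefficients, adjusted Rand similarity) are included.

**Spatial analysis.** Edge/core zoning of somata relative to the sample
boundary with zone-mean comparisons (excision-artifact quantification), and
per-module convex hulls, centroids, pairwise overlaps and a tiling score for
mosaic analysis in the retinal plane.

**Layout and circuits.** Spectral distance embedding (classical MDS of
geodesic hop distances, ||x_i − x_j|| ≈ D_ij, residual stress reported),
anatomical layering, strong-link subgraphs of focus neurons, per-neuron
circuit reports (strong partners by class, Off/On cone-bipolar input
tallies, weak-link feedback candidates) and cross-measure node rankings.

**Synthetic ground truth.** A generator emulating the raw data: typed
neurons in a 132×114×80 μm box, spatially planted modules, Poisson
multi-contacts with lognormal areas, a 14% reversed-duplicate listing rate,
glia contacts, and boundary truncation — so every stage is testable with a
known answer.

## Worked example

```python
from synaptoflow import (GeneratorParams, generate_sample, filter_contacts,
                         aggregate_links, infomap_partition, module_flow_table,
                         weighted_degree)
from synaptoflow.ingest import drop_uncataloged_contacts
from synaptoflow.communities import partition_similarity

sample = generate_sample(GeneratorParams(), seed=7)
table, n_glia = drop_uncataloged_contacts(sample.contacts, sample.catalog)
graph = aggregate_links(filter_contacts(table, 0.16), 0.16,
                        node_ids=sample.catalog.ids)
print(f"{graph.n_nodes} neurons, {graph.n_links} links "
      f"({n_glia} glia contacts dropped)")
print(f"mean weighted degree: {weighted_degree(graph).strength.mean():.1f}")

part, flow = infomap_partition(graph, seed=7, trials=10)
print(f"codelength: {flow.codelength:.3f} bits, {part.n_modules} modules")
print(module_flow_table(flow, part, sample.catalog).head(6).to_string(index=False))
print(f"recovery ARI vs planted truth: "
      f"{partition_similarity(part, sample.truth):.3f}")
```

prints

```
950 neurons, 13189 links (2087 glia contacts dropped)
mean weighted degree: 65.1
codelength: 7.778 bits, 6 modules
 module  total_flow  n_members key_classes
      1    0.196862        169   cBC, NFac
      2    0.176766        165   cBC, NFac
      3    0.173392        163   cBC, NFac
      4    0.153146        159    cBC, rBC
      5    0.153050        147   cBC, NFac
      6    0.146784        147   cBC, NFac
recovery ARI vs planted truth: 1.000
```

The six flow modules are exactly the six spatially planted ones (adjusted
Rand index 1.0), each holding 15–20% of the total random-walk flow and led
by cone bipolar and near-field amacrine cells, the most numerous classes.
Minimizing the codelength below the single-module entropy (9.83 bits for
this graph) is what justifies the decomposition.

The same pipeline runs from the shell:

```sh
synaptoflow simulate --seed 7 --out sample/
synaptoflow ingest --contacts sample/contacts.csv --threshold 0.16 --out adj.csv
synaptoflow modules --adj adj.csv --method infomap --seed 42 --trials 20 --out membership.txt
synaptoflow metrics --adj adj.csv --out metrics.csv --weighted
synaptoflow spatial --catalog sample/cells.csv --metrics metrics.csv \
    --membership membership.txt --margin 10 --plane 132 114
```

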