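# hapconn

Haplotype connectivity for phylogeography: is a region of high
intraspecific genetic diversity a **hot-spot** (a refugium where diversity
accumulated in situ over a long time) or a **melting-pot** (a zone of
recent secondary contact between previously isolated gene pools)?

Both scenarios leave high diversity, so diversity alone cannot tell them
apart. What differs is the *shape* of the diversity: in a hot-spot the
sampled haplotypes are dispersed across the haplotype phylogeny, in a
melting-pot they clump into a few divergent groups. `hapconn` quantifies
this with **haplotype connectivity**.

## The scores

Given a symmetric genetic distance matrix *D* on a haplotype set *X* and a
subset *Y* ⊆ *X* (the haplotypes found in a region), let *G<sub>t</sub>(Y)*
be the threshold graph on *Y* with edges between pairs at distance ≤ *t*.
The haplotype connectivity

> HC(*Y*) = min { *t* ≥ 0 : *G<sub>t</sub>(Y)* is connected }

equals the maximum edge weight of a (bottleneck) minimum spanning tree of
the complete distance graph on *Y*, and is computed that way in
O(|*Y*|²). To compare regions of different sample sizes, raw scores are
normalized against the extrema over all subsets of the same size *k*:

> HC\*(*Y*) = (HC(*Y*) − HC<sub>min</sub>(*k*)) / (HC<sub>max</sub>(*k*) − HC<sub>min</sub>(*k*)) ∈ [0, 1]

where HC<sub>min</sub>(*k*) (the bottleneck *k*-MST value) comes from a
single union-find sweep over the sorted distances, and
HC<sub>max</sub>(*k*) from a binary search over thresholds with a
max-flow vertex-connectivity test (every *k*-subset of *X* is connected
at threshold *t* iff κ(*G<sub>t</sub>(X)*) > |*X*| − *k*).

Diversity is scored the same way, with either measure:

* **PD(Y)** — phylogenetic diversity, the total length of the minimal
  subtree of the haplotype phylogeny spanning *Y*; PD<sub>max</sub>(*k*)
  by the (provably optimal) greedy chain, PD<sub>min</sub>(*k*) by
  dynamic programming over the rooted tree;
* **AD(Y)** — average squared pairwise distance; its *k*-subset extrema
  are NP-hard (MAXISUM dispersion), so they are solved exactly by
  branch-and-bound up to a size cap, never approximated silently.

**Interpretation:** among regions of high normalized diversity, high
HC\* suggests a melting-pot, low HC\* a hot-spot. Low-diversity regions
are not assessed.

## Worked example

The packaged toy phylogeny `figure1_tree("b")` has 13 sampled haplotypes
b1..b13 in two groups joined by a path of unsampled intermediates (all
edges length 1). Score two 4-haplotype regions — one spanning both
groups, one confined to a single group:

```sh
hapconn score --tree figure1b_edges.tsv --labels figure1b_labels.tsv \
              --regions regions.tsv --diversity pd
```

```
region  n  PD    PD_min  PD_max  PD*   HC   HC_min  HC_max  HC*   annotation
mixed   4  13.0  3.0     16.0    0.77  9.0  1.0     13.0    0.67  melting-pot-like
local   4  3.0   3.0     16.0    0.0   1.0  1.0     13.0    0.0   low-diversity (not assessed)
```

The `mixed` region contains haplotypes from both groups: high diversity
(PD\* = 0.77) *and* high connectivity (HC\* = 0.67 — its haplotypes
cannot be linked without a 9-step jump across the unsampled bridge), the
melting-pot signature. The `local` region has the minimum possible
diversity and connectivity for its size, so it is not assessed.

The same library calls in Python:

```python
import hapconn as h

tree = h.figure1_tree("b")
D = h.phyletic_distances(tree)
h.haplotype_connectivity(D)                               # 5.0
h.haplotype_connectivity(D, ["b2","b4","b6","b8","b10","b12"])  # 5.0
h.threshold_graph(D, ["b2","b4","b6","b8","b10","b12"], 2).is_connected  # False
```

Other subcommands: `hapconn hc`, `bounds`, `pd`, `gds` (pairwise-distance
histogram / genetic diversity spectrum), `simulate` (synthetic hot-spot
and melting-pot datasets), `distances` (build a matrix from FASTA,
allele-size TSV, Newick or edge-list input).

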