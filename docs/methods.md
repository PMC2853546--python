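# Methods

## Model

The unit of analysis is a *haplotype* — a distinct sampled DNA sequence
or allele-profile variant. The data are (i) a symmetric, non-negative,
zero-diagonal dissimilarity matrix *D* on the haplotype set *X*, and
(ii) a table assigning haplotypes to geographic regions (a haplotype may
occur in several regions; occurrence counts are deliberately ignored —
the scores depend on *which* haplotypes were found in a region, not how
often).

*D* can be supplied directly (PHYLIP or TSV) or derived from:

* aligned sequences — Hamming distance (per-site mismatch count). Gap
  and ambiguity characters are excluded pairwise by default, the least
  destructive convention; counting them as mismatches is an option.
* microsatellite allele-size profiles — the pairwise haplotypic
  difference, Σ over loci of |size difference|.
* a haplotype phylogeny or network with labeled (sampled) and unlabeled
  (hypothetical intermediate) vertices — phyletic distance, the shortest
  path length between labeled vertices. Branch lengths are summed; edge
  counts are the unit-length special case. Cyclic haplotype networks are
  accepted here (shortest paths); phylogenetic diversity below is
  restricted to trees, where the spanning subtree is well defined.

No algorithm in the package assumes the triangle inequality; symmetry
and non-negativity suffice.

## Haplotype connectivity

HC(Y) is the smallest threshold t at which the threshold graph G_t(Y)
(edges between pairs of Y at distance ≤ t, inclusive comparison) is
connected. It equals min over spanning trees T of the complete distance
graph on Y of the maximum edge weight of T, and any minimum spanning
tree attains that bottleneck. We compute an MST with a dense Prim sweep,
O(|Y|²) — already optimal for a complete graph — rather than the
linear-time median-recursion bottleneck-MST algorithm, which has the
same output at far higher code complexity. scipy's sparse-graph MST was
rejected because it treats 0-weight entries as absent edges, and
duplicate haplotypes at distance 0 are legal inputs here.

Degenerate cases, fixed as package policy: HC of a singleton is 0; HC of
the empty set is an error; every returned HC value is 0 or an exact
matrix entry (no epsilon is applied to threshold comparisons, so
integer-valued inputs give exact integer results).

### Extrema over k-subsets

* **HC_min(k)** (the bottleneck k-MST value): the smallest threshold at
  which some connected component of G_t(X) has ≥ k vertices — pruning a
  spanning tree of that component to k vertices exhibits a witness
  subset. One Kruskal-style union-find sweep over the sorted distances
  serves all k.
* **HC_max(k)**: the smallest t such that *every* k-subset is connected
  at t, which by Menger's theorem is κ(G_t(X)) > |X| − k, with κ the
  vertex connectivity (a complete graph has κ = n − 1 by convention, so
  k = |X| is covered). Computed by binary search over the sorted
  distinct distances with networkx's max-flow vertex-connectivity test,
  memoized per threshold. `ConnectivityProfile` caches thresholds, the
  merge trajectory and κ values so that extrema for many k are cheap.

HC_min is non-decreasing in k (prune a leaf off a bottleneck tree).
HC_max is **not** monotone: with D(x,y)=10 and D(x,z)=D(y,z)=1,
HC_max(2)=10 yet HC_max(3)=1 — adding a mediating haplotype can only
help connectivity. The test suite pins this counterexample.

## Diversity

* **PD(Y)**: total edge length of the minimal (Steiner) subtree spanning
  the vertices labeled by Y, computed by pruning unlabeled leaves.
  Sampled haplotypes may label internal vertices — parsimony haplotype
  networks routinely do — so the dynamic program for PD_min(k) tracks
  labeled-vertex counts at every vertex, not only leaves: dp[v][j] is
  the minimal length of a subtree topped at v containing j labeled
  vertices, combined over children by knapsack, O(n·k²) total.
  PD_max(k) uses the greedy chain (start from the farthest labeled pair,
  repeatedly add the labeled vertex farthest from the current subtree),
  which is provably optimal for PD maximization; the suite nevertheless
  checks both extrema against exhaustive enumeration on random trees.
* **AD(Y)**: the average squared pairwise distance, (1/C(|Y|,2)) Σ
  D(x,y)^p with p = 2 by default. The source phrase for this measure
  says "squared", but the printed case-study values cannot be re-derived
  without the unpublished raw matrix, so the unsquared p = 1 variant is
  exposed as an option rather than silently chosen. AD extrema over
  k-subsets are NP-hard (MAXISUM facility dispersion), so `ad_extrema`
  is exact-only: plain enumeration below 16 haplotypes, best-first
  branch-and-bound (optimistic pairwise-sum bound, greedy incumbent) up
  to a default cap of 25, and a CapacityError beyond — exact instances
  up to ~60 haplotypes are known to be feasible, but above the cap the
  user must opt in explicitly rather than receive a heuristic.
* **GDS**: the genetic diversity spectrum, i.e. the frequency
  distribution of pairwise distances. Exact counts per distinct value
  for integer-valued matrices; optional fixed-width binning otherwise.
  Bimodality (many short within-cluster and many long between-cluster
  pairs) is itself a melting-pot signature.

## Normalization and interpretation

Raw scores are normalized as (raw − min_k)/(max_k − min_k) against the
extrema over all k-subsets of the **full** haplotype set X (not
per-region pools), with 0 returned when the range is degenerate. The
extrema are cached per distinct k. Display rounding is 2 decimals,
half-up; full precision is kept internally and in JSON output.

The hot-spot / melting-pot annotation is advisory: among regions whose
normalized diversity reaches a configurable quantile (default the
median), HC\* at or above a configurable cut (default 0.5) is annotated
melting-pot-like, below it hot-spot-like; other regions are
"low-diversity (not assessed)", because low diversity forces low
connectivity and the comparison is uninformative there. The boundary is
inclusive (≥ cut ⇒ melting-pot-like) so that a region sitting exactly at
0.50 — the configuration of the canonical worked example — is flagged.
The inference is comparative; no universal numeric threshold exists, and
the cuts are user-configurable for that reason.

## Synthetic scenarios

`simulate_scenario` generates the two structures the method is designed
to distinguish, for tests and power studies:

* *hot_spot*: a random unit-edge tree grown by sequential uniform
  attachment, with the sampled haplotypes placed uniformly at random
  over its vertices (dispersed labels);
* *melting_pot*: two (or more) such trees joined by unlabeled bridge
  paths — standing in for extinct or unsampled intermediates between
  long-isolated gene pools — with sampled haplotypes confined to the
  clusters and the focal region drawn evenly from all clusters, as in a
  zone of secondary contact.

Defaults, chosen once as a realistic small phylogeographic survey:
40 tree vertices, 20 sampled haplotypes, 2 clusters, bridge separation
10 mutational steps, focal region = half the haplotypes, the rest in a
background region (so normalization is non-degenerate). Unit edges make
total tree length equal vertex count − 1, so hot-spot and melting-pot
instances with equal vertex counts are matched in total tree length and
in haplotype number — the diversity distributions then overlap and any
separation must come from connectivity. The 50-seed study in the
acceptance suite finds mean focal HC\* ≈ 0.69 (melting-pot) versus
≈ 0.39 (hot-spot) under these conditions.

What the generator does not emulate: coalescent genealogies, haplotype
frequencies, geography/isolation-by-distance, homoplasy, and sampling
error. Passing the simulation study shows the scores separate the two
idealized structures; it does not quantify power on real surveys, where
cluster separation, sampling depth and marker choice all matter.

## Numerical choices and limitations

* Thresholds are compared exactly as stored (no epsilon); all packaged
  toy inputs are integral, so the worked examples are exact.
* Ties in the PD greedy chain and in table sorting are broken
  deterministically (label order; region name), making CLI output
  byte-stable across runs.
* Exact-search problem sizes: the oracle-equivalence tests run
  enumeration up to 9 haplotypes (connectivity), 10 labeled vertices
  (PD) and 10 haplotypes (AD branch-and-bound); the published-scale
  case studies (69 and 34 haplotypes) are well within the algorithms'
  polynomial parts but their raw inputs exist only in print, so the
  suite reproduces their normalization arithmetic from the printed
  raw/min/max values instead.
* HC_max's vertex-connectivity step is the expensive one (max-flow per
  candidate threshold); for many-k workloads use one
  `ConnectivityProfile` so the per-threshold κ values are shared.
* Statistical significance of HC scores, geographic side-constraints on
  subsets, and approximation schemes for AD extrema beyond the exact cap
  are out of scope.
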