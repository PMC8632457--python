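# Methods

## Model and procedure

`adsim` scores pairwise genetic similarity between diseases whose gene
associations are given as sets of gene symbols, using three measures that
probe different data modalities, and then integrates them.

**Network similarity.** Every node of the undirected PPI network is
profiled by degree, clustering coefficient, betweenness centrality,
average shortest path length and neighborhood connectivity (mean degree of
neighbors). A disease's topology vector T = (R, C, B, S, H) is the
arithmetic mean of these five properties over the disease's genes that
occur in the network, and NetSim is the Pearson correlation between two
diseases' T vectors. Note the correlation treats the five heterogeneous
components as paired observations; because the components live on very
different scales (degree and neighborhood connectivity dominate), NetSim
concentrates near 1 and is the least discriminative of the three measures.
This is a property of the measure itself, preserved deliberately; a
`standardize_properties` flag (default off) offers column z-scoring across
diseases as an extension.

**Functional similarity.** Log-likelihood scores of the functional network
are min–max normalized with the global extrema of the input network. The
disease-pair score is the symmetric best-match average over both gene
sets: genes shared by both sets contribute 1, genes linked across sets
contribute their normalized weight, unlinked genes contribute 0. Genes
absent from the functional network stay in the sets (best match 0 unless
shared) — dropping them would silently inflate similarity. Duplicate genes
are collapsed before the set sizes m and n are counted.

**Semantic similarity.** Direct term → gene annotations are propagated up
the ontology's IS_A DAG (true-path rule), after which
IC(t) = −log(n_t / N) with n_t the propagated gene count and N the total
number of annotated genes. Propagation makes IC anti-monotone along IS_A
edges, which is what gives the most informative common ancestor (MICA) its
meaning. Ancestor sets include the term itself, so SemSim(d, d) = IC(d).
The log base is configurable (`ic_log_base`, default natural log); it
cancels under the default normalization. SemSim is normalized to [0, 1] by
the maximum IC over the mapped terms by default so the three measures are
scale-compatible under integration; raw mode is available.

**Integration and downstream selection.** IntegratedSim is the geometric
mean (cube root of the product) of the three scores. A negative NetSim is
clamped to 0 by default: a negative correlation carries no meaning for the
threshold and clustering logic downstream, and clamping is monotone; a
signed mode (real cube root) exists behind a flag. Candidate pairs are the
intersection of the top-k pairs (default k = 50) under each measure, with
deterministic lexicographic tie-breaking at the k-boundary and no tie
expansion. Candidates are ranked by shared-gene count. The candidate
disease–gene network is bipartite (association edges) plus
disease–disease similarity edges; a gene's degree therefore equals the
number of candidate diseases carrying it, and genes with degree ≥ 3
(default) are reported as relevant genes.

**Clustering.** Diseases are clustered on Euclidean distances between
their full integrated-similarity profile rows (the diagonal is set to 1
first, so each row includes the disease's own column — a convention is
required and 1 is the natural self-similarity). Linkage is agglomerative,
default average (UPGMA), the common choice for similarity-profile
heatmaps; single, complete and Ward are selectable. "Significant" clusters
are the maximal dendrogram clades of size ≥ 2 in which every within-clade
pair's integrated similarity exceeds the threshold (default 0.3). The
extraction rule respects the dendrogram structure; a
connected-components-of-the-thresholded-graph alternative is available
(`extraction="components"`) for sensitivity analysis. Diseases with
undefined integrated entries are dropped from clustering with an explicit
report, since the row distance needs complete rows.

## Conventions for under-specified corners

* Betweenness is normalized to [0, 1] by 2/((n−1)(n−2)) within each node's
  connected component of size n; raw betweenness would let B dominate the
  topology vector. Average path length is likewise computed within the
  component (infinite distances are not averageable). Both follow the
  conventions of common GUI network-analysis tools.
* Genes absent from the PPI network are excluded from the disease average,
  not imputed as zeros; a disease with no genes in the network has an
  undefined vector and is dropped with a warning.
* A pair whose correlation is undefined (a constant topology vector) is
  recorded as missing (NaN), excluded from ranking, and blocks clustering
  for the affected disease rather than being filled with a number.
* Gene symbols are uppercased and whitespace-stripped; no alias resolution
  is attempted, so set intersections are exact on normalized symbols.
* Self-loops in edge lists are dropped with a warning; they carry no
  information for any formula here. Only IS_A edges of the ontology are
  used; obsolete terms are excluded; the root is auto-detected as the
  unique parentless term or must be supplied.

## Synthetic benchmark

The generator emulates the five inputs at desk scale (defaults: 500 genes,
12 diseases, 3 planted clusters, 15 genes per disease, within-cluster gene
share 0.8, LLS weights uniform on [1, 4], functional edge probability 0.4
inside cluster pools and 0.005 elsewhere, a balanced depth-4 branching-3
ontology tree, preferential-attachment PPI with 3 edges per new node).
The cluster signal is planted in all three channels, because candidate
selection requires agreement of all three: disjoint per-cluster gene pools
(network and shared-gene signal), elevated functional edge density inside
pools (functional signal), and placement of cluster members on leaves of a
common depth-1 ontology subtree (semantic signal). Diseases are assigned
to clusters round-robin. A preferential-attachment PPI topology is used
because averaging topological properties is only informative on a
heavy-tailed degree distribution.

What the benchmark does *not* emulate: real PPI/functional network sizes
(three orders of magnitude larger), correlated noise between channels,
incomplete annotation, multi-parent ontology terms for disease leaves, or
gene-symbol aliasing. Passing tests therefore demonstrate the pipeline's
correctness and its ability to recover planted structure under clean
conditions, not performance on real disease data.

Under the default conditions the pipeline recovers the planted partition
with adjusted Rand index 1.0 across 20 generator seeds (the acceptance
suite requires ≥ 0.9). Two quirks of the benchmark are worth knowing:

* The three-measure top-10 intersection at 12 diseases typically contains
  only 1–2 candidate pairs, because NetSim's ranking is weakly
  discriminative (see above). With so few candidate diseases no gene
  reaches network degree 3, so the relevant-gene table is often empty at
  this scale; the degree filter becomes informative only with larger
  candidate networks.
* Setting `within_cluster_share = 0` removes the gene-channel signal but
  not the semantic placement, which is structural; within-subtree pairs
  that share a gene or two by chance can still exceed the 0.3 threshold,
  so the null is not fully flat. The planted/null contrast remains large
  (within-cluster integrated scores ≈ 0.8 at share 0.8 versus null maxima
  ≈ 0.4–0.5).

## Numerical choices

* Pearson correlations are computed with the explicit covariance formula
  so that the score is exactly symmetric in its arguments.
* Similarity matrices are validated symmetric within 1e-12 at
  construction and again before writing; files carry 12 significant
  digits and round-trip within 1e-9.
* MICA ties (equal IC) are broken by greater DAG depth, then
  lexicographically smallest term id. Ranking ties are broken
  lexicographically by sorted disease-id pair. scipy's linkage is
  deterministic for a fixed label order, and labels are sorted, so
  dendrograms are reproducible.
* Everything downstream of the generator is deterministic; re-running an
  identical configuration reproduces byte-identical output files.

## Problem sizes

Tests and the acceptance script run the full pipeline at the default
benchmark scale (500 genes / 12 diseases, ~1.7 s per end-to-end run) and
use exhaustive brute-force oracles at small sizes: all-pairs path
enumeration on connected graphs of ≤ 7 nodes, literal best-match-average
evaluation on gene sets of ≤ 4, and ancestor-set enumeration on DAGs of
≤ 10 terms. Recovery statistics aggregate 10–20 independent generator
seeds.
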