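# Methods

This note documents the statistical conventions, defaults and numerical
choices behind each stage of the package, and what its synthetic-data tests
do and do not demonstrate about real data.

## Data model

The interactome is an undirected simple graph over gene symbols: loaders drop
self-loops and collapse duplicate edges (counts logged), and symbols are
matched case-sensitively after whitespace trimming (an `uppercase` option
normalises case at load time, since public gene lists mix conventions). The
package consumes one pre-merged edge list; `merge_interactomes` unions
several. Ortholog tables keep only one-to-one pairs — any source with several
targets, or target with several sources, is dropped — because without
explicit homology confidence scores there is no principled way to pick among
ambiguous pairs.

## Subnetwork topology

All seven statistics are computed on the subgraph induced by the mapped gene
set, with unweighted hop distances. The induced subgraph of a disease gene
set on a sparse interactome is almost always disconnected, so the
disconnected-graph conventions matter:

- **mean degree** defaults to edges per mapped node (E/N). For a subgraph
  whose observed edge count (~250) roughly equals its node count (~235), only
  E/N reproduces the reported mean degree near 1; the textbook 2E/N is
  available via `degree_convention`.
- **closeness** uses the Wasserman–Faust component scaling
  ((r−1)/(n−1))·((r−1)/Σd), which down-weights nodes in small components
  smoothly and gives isolated nodes 0.
- **mean shortest distance** averages over connected unordered pairs only,
  within the induced subgraph, and is undefined (NaN) when no connected pair
  exists. A consequence worth knowing: random node sets on a sparse
  background have few connected pairs, mostly adjacent ones, so their mean
  distance can be *smaller* than a planted module's — the lower-tail test on
  this statistic is only informative on reasonably dense subgraphs.
- **betweenness** is normalised by (n−1)(n−2)/2 pairs, endpoints excluded;
  **clustering** gives degree-<2 nodes a coefficient of 0.

## Localization permutation test

Each replicate draws, uniformly without replacement from all interactome
nodes, a set of the same size as the mapped input, and recomputes the
statistics on its induced subgraph. Edge count, largest component, mean
degree, closeness, clustering and betweenness use the upper tail; mean
shortest distance the lower tail. p-values are plain empirical fractions
r/n_perm with ties counted as hits — the convention under which a permutation
tool can print p = 0.000 — with (r+1)/(n_perm+1) available via `pseudocount`.
Replicates whose mean shortest distance is undefined are treated as +∞ (never
counted for the lower tail) and logged; if the *observed* value is undefined
it is likewise treated as +∞, so every replicate with any finite or undefined
value counts and p → 1, the conservative direction. Degree-matched sampling
is deliberately not the default: the null being tested is "equally sized
random gene sets", and a single seeded generator drawing replicates in
sequence keeps runs bit-reproducible.

## Separation score

Distances are computed on the interactome's largest connected component
(LCC) so every mapped pair is reachable; the all-pairs matrix comes from
scipy's csgraph BFS. The default `nearest` convention is the one that defines
the separation score: each node contributes its shortest distance to the
nearest member of the other set, d_A/d_B use the nearest *other* member of
the node's own set, and d_AB averages the |A|+|B| node terms. A gene shared
by both sets counts itself across sets at distance 0 — shared membership is
precisely what drives S_AB negative under this convention. The degenerate
case A = B instead applies the other-member rule symmetrically, making
S_AA exactly 0; `self_distance_zero=False` extends that exclusion to all
shared genes, and `convention="all_pairs"` switches to plain all-pairs means.
Singleton within-set distances are undefined and dropped from the average
with a warning. The permutation null draws both random sets independently
(they may overlap, as two independently curated gene lists may), and the
one-sided p counts replicates with S at or below the observed value.

## Overlap and enrichment statistics

Fisher's exact test is two-sided by the point-probability rule (summing all
tables with the observed margins whose probability does not exceed the
observed table's), matching R's `fisher.test`; scipy provides the
implementation, and the test suite checks it against exhaustive enumeration.
The background universe is an explicit required input — a gene list (then
membership is enforced, with violations dropped and warned) or an integer.
The reported odds ratio is the sample estimate ad/bc, with the
conditional-MLE estimate alongside; on published data neither can be pinned
exactly without knowing the original universe, so both are exposed. GMT
enrichment uses the upper-tail hypergeometric survival function per set, with
Benjamini–Hochberg and Bonferroni columns computed over all tested sets
(via statsmodels, verified against the step-up definition in tests);
p-values below R's 2.2e-16 reporting floor are kept at full precision.

## Expression-weighted cell-type enrichment

Specificity of gene g in cell type c is mean(g in c) / Σ_c' mean(g in c'),
so rows sum to 1 and the matrix is invariant to global rescaling of the
expression values. Genes with all-zero means are dropped with a warning. The
test statistic is the summed specificity of the mapped query genes per cell
type (sum and mean are equivalent up to the common factor of query size);
bootstraps draw equally sized gene lists uniformly without replacement from
all genes of the specificity matrix — the background can be restricted by
subsetting the matrix before testing. p is the ties-inclusive bootstrap
fraction, Bonferroni-adjusted across cell types. Transcript-length/GC-
matched sampling is not implemented; for marker-driven signals of the
magnitude the generator plants (5× expression), uniform sampling recovers
the truth comfortably, but on real data subtle confounding with expression
level is not controlled. Cross-species queries should be ortholog-mapped
first (`map_orthologs`); the default bootstrap count of 100,000 suits
production runs, while the tests and the acceptance script use 200–10,000
draws, which is ample for the strong planted effects they check.

## Synthetic data

- **Interactome**: Erdős–Rényi (default, mean degree ~5 at 10⁴ nodes —
  sparse, like curated PPI networks), Barabási–Albert or
  duplication–divergence, with zero-padded symbolic gene names for stable
  output ordering.
- **Planted module**: a random-walk (snowball) sample, which guarantees the
  selected nodes induce a connected subgraph before densification, then
  independent internal edges with probability `module_edge_prob` (default
  0.3, an order of magnitude above background density — a strong but not
  trivial localization signal at module size 30).
- **Overlapping sets**: two sets carved from one planted module with a
  controlled number of shared genes; mean separation decreases monotonically
  as the shared fraction grows, and equals 0 when the sets coincide.
- **Expression**: negative-binomial counts (baseline mean μ = 2, dispersion
  θ = 2 — overdispersed at the scale of shallow scRNA-seq), with a disjoint
  marker block per cell type whose within-type mean is μ·`marker_fold`
  (default 5). Defaults of 4 cell types × 100 cells and 40 markers per type
  keep desk-scale runs fast; no doublets, batch effects or dropout structure
  beyond the NB are modelled.
- **GMT collection**: one planted set containing 80% of the query plus
  random filler, among 49 uniform decoy sets.

What passing the synthetic tests shows: the statistics are implemented
correctly (brute-force oracle agreement), calibrated under the null
(uniform p-values), and able to recover strong planted signals. What it does
not show: robustness to the degree heterogeneity, ascertainment bias and
annotation noise of real interactomes and expression atlases — on real data,
degree-binned sampling (available as an option) and careful universe choice
matter.

## Pipeline

`run_pipeline` executes overlap → localization → proximity → co-expression
overlap → EWCE → GMT enrichment; a stage with missing optional inputs is
skipped with a warning, any failure aborts naming the stage. One global seed
derives per-stage seeds as seed + stage-index, so a stage rerun in isolation
reproduces its pipeline output exactly; the manifest records stage seeds,
output names and SHA-256 input digests. Defaults follow the conventional run
sizes for this analysis: 5,000 localization permutations, 1,000 proximity
permutations, 100,000 EWCE bootstraps, FDR < 0.01 for enrichment and
Bonferroni < 0.05 for cell types.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` run on 2,000-node backgrounds
with 30-gene planted sets (1,000 permutations), 400-gene × 400-cell
expression matrices (up to 10,000 bootstraps), and brute-force oracle
comparisons on graphs of ≤ 30 nodes and tables with margins ≤ 12 — sizes
chosen so the full validation completes in minutes while keeping the planted
effects at realistic magnitudes. Null-calibration checks use 200 trials of
200 permutations and verify the 5% rejection rate within binomial bounds
(plus a Kolmogorov–Smirnov check where the statistic is continuous;
empirical p-values of discrete statistics such as edge counts are
conservative by construction under the ties-inclusive rule).

## Known limitations

- Distances are unweighted; confidence-scored or directed interactions are
  out of scope.
- The localization null is not degree-matched by default (see above).
- Mean-shortest-distance localization is weakly powered on sparse induced
  subgraphs by the within-subgraph connected-pairs convention.
- EWCE lacks covariate-controlled sampling and hierarchical cell-type
  levels.
- Published odds ratios depend on the (unstated) background universe of the
  original analyses; with the 20,000-gene protein-coding default the
  recomputed values land within ~2% of the published ones.
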