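# Methods notes

This note documents the models, numerical choices and limitations behind the
package; the README gives the user-level overview.

## Distance and percolation

The Jaccard dissimilarity is computed on boolean site rows via
`scipy.spatial.distance.pdist`. A site with an empty species set has an
undefined Jaccard distance and is a hard error; the reader drops (or, in
strict mode, rejects) all-zero rows and columns before this point.

Percolation deletes **distinct distance values**, not individual edges: all
edges tied at the current largest value go in one step. Distances are rounded
to 12 significant digits before grouping so floating-point noise cannot split
an intended tie into two steps. The critical threshold is reported as the
deleted value at which the largest component first drops below the number of
sites — the fragmenting value itself, not a midpoint between consecutive
values. Edges exactly at the threshold are **not** retained by default
(strict `<` retention); a `retention="<="` flag exists for sensitivity
checks. In the average cluster size

    <L> = (1/N) Σ_{l < l_max} l² n_l

exactly one cluster of maximal size is excluded; when several clusters tie
for the maximum, the others stay in the sum. While the graph is connected
`<L>` is 0, and a single-cluster multiset returns 0 (N = 0). If the network
only fragments at the very last deletion step (e.g. all distances tied),
there is no informative threshold and the result carries a `degenerate`
flag. The full deletion trace is kept for inspection and export.

## Modularity maximization

Edge weights of the retained network default to `similarity = 1 − distance`
("weighted" analysis); a `binary` flag sets unit weights. The null
probability is the configuration model, `P_ij = k_i k_j / 2m`, with weighted
degrees and `m` the total link weight, so Q of the one-module partition is
exactly 0 and Q ≤ 1.

The annealer keeps per-module internal weight `e_c` and degree sum `d_c`, so
a single-node move costs O(degree):

    ΔQ(i: a→b) = (w_ib − w_ia)/m − k_i (d_b − d_a + k_i) / 2m²

Moves are single-node reassignments (target: a random neighbour's module
with probability 0.9, otherwise a fresh singleton) plus collective
merge/split proposals (random module pair merge; random bisection of one
module followed by one refinement sweep), accepted with probability
min(1, exp(ΔQ/T)).

Schedule defaults: geometric cooling factor 0.995, `max(100, n²)` node moves
and `n` collective moves per temperature, stop after 50 temperatures without
improvement of the best Q ever seen. Each run starts from singletons with a
zero-temperature greedy phase over the same move set, and performs **3
independent anneal cycles** (reheats), returning the best partition across
cycles. The initial temperature is `max(1/(2m), 0.05)`: the pure `1/(2m)`
start is too cold on small dense graphs to escape the greedy basin — with
the floor and the reheat cycles the optimizer matches exhaustive search on
all tested ≤ 8-node weighted graphs (50/50 seeded cases), which is the bar
the test suite enforces. All schedule fields are configurable.

Null replicates rewire the observed topology with `networkx`
double-edge swaps (10× the edge count; degree sequence preserved exactly)
and reshuffle the observed weights onto the rewired edges, then anneal with
a reduced schedule (cooling 0.99, patience 10, one cycle). Graphs too sparse
to swap fall back to a weight-permutation null with a warning. Reported:
null mean, SD, percentile 95% CI, and the add-one empirical p-value
`(1 + #{Q_null ≥ Q_obs}) / (n_rand + 1)`; "significant" means Q_obs above
the CI's upper limit. Calibration on unstructured Erdős–Rényi-style graphs
keeps the observed Q inside the null CI in ≥ 90% of seeded trials.

The restart consensus clusters the node co-classification matrix
(average-linkage, cut at 0.5 co-assignment); each restart's modules are
matched to consensus modules by maximum-overlap assignment and the per-node
agreement fraction is reported, with nodes below 0.9 flagged unstable. Both
the restart SD of Q and the null SD are reported, since "±" conventions
differ between the two readings. The pipeline reports the consensus
partition unless a single restart strictly beats its Q.

## Locality roles

The literature defines local topological richness and regional topological
linkage verbally; the concrete formulas here are this package's choices:

* `l` = z-score, among the sites of the same module, of the site's count of
  species exclusive to that module. Single-site modules (or modules with
  zero spread) make the z-score undefined; those sites get l = 0 and an
  explicit flag rather than NaN, keeping the role table total.
* `r` = `1 − Σ_M f_M²`, where f_M is the fraction of the site's
  species-module incidences falling on module M (each species contributes
  one incidence per module its whole range spans). r = 0 iff every species
  of the site is confined to a single module; a site whose species spread
  evenly over q modules has r = 1 − 1/q.

Cut lines default to l = 1.0 z-units and r = 0.5. These defaults are
artifact choices for the quadrant logic, not published values; role labels
near the cuts should be read qualitatively. Roles are invariant under module
relabeling by construction.

The shared-species ledger counts every species once, under the **exact** set
of modules its occurrences span, so exclusive / pairwise-shared /
shared-by-all counts are disjoint and sum to the species total.

## Between-group correspondence analysis

CA is the SVD of the standardized Pearson residuals of the relative
frequency table; total inertia equals χ²/n (verified against
`scipy.stats.chi2_contingency` to 1e-10). Singular values below
`max(I,J)·eps·σ_max` are zeroed, so an exactly independent table yields zero
inertia and all-zero scores. Axis signs are arbitrary; tests compare only
sign-invariant quantities.

Group centroids are mass-weighted mean row profiles — equivalently the CA of
the module-summed count table, which preserves column margins, so the
centroid-table inertia **is** the between-group component of the full-table
inertia and the between/total ratio is exact, in [0, 1], reaching 1 when
every site matches its group centroid. Sites enter the group space as
supplementary rows via the column standard coordinates; their mass-weighted
group means then coincide with the group scores exactly. Retained axes:
min(groups − 1, classes − 1). Class contributions are fractions of each
axis's inertia and sum to 1 per axis.

## Synthetic metacommunity

The generator plants modules with private species pools: a private species
occurs at a site of its own module with probability `p_in`, elsewhere with
`p_out`; cosmopolitan species occur anywhere with `p_cosmo`. All draws are
independent Bernoulli from one seeded `numpy` generator, so a seed fixes the
matrix bitwise. Private pools of module k get the k-th non-cosmopolitan
biogeographic class (cycling over the eight), cosmopolitans get COSMP — the
1:1 module/class design the BGCA should recover.

Defaults (4 modules × 7 sites, 30 private species each, 10 cosmopolitans,
p_in = 0.9, p_out = 0.05, p_cosmo = 0.7) describe a well-separated
basin-scale metacommunity at the size of the motivating application
(28 localities, ~130 species). What the generator does **not** emulate:
spatial gradients within modules, species-richness heterogeneity between
sites, abundance, or detection error — a green recovery test therefore
establishes correctness of the machinery on well-separated presence/absence
structure, not robustness to weak or spatially confounded structure.
`expected_jaccard` provides a Monte-Carlo oracle (mean ± SE of within- vs
between-module distances) to verify separation before recovery tests.

## Reproducibility and degenerate inputs

Every stochastic stage takes an explicit seed; the pipeline derives
per-stage seeds from one master seed by hashing (blake2b of
`"{seed}:{stage}"`, reduced below 2³¹). Reruns with identical inputs,
configuration and master seed reproduce every artifact.

Degenerate inputs handled explicitly: edgeless graphs (modularity error /
trivial partition), single-edge graphs (one module, Q = 0), all-tied
distance matrices (degenerate percolation flag), single-site modules
(flagged l = 0), tables with zero rows/columns (dropped or rejected),
rank-deficient count tables (zero eigenvalues, zero scores).

## Known limitations

* The simulated annealer is exact only in the tested small-graph regime;
  on large networks it is a heuristic like any modularity maximizer, and
  modularity itself has a resolution limit.
* Only the Jaccard index is built in (the distance hook accepts any
  precomputed matrix in `DistanceMatrix` form).
* The role cut lines are conventions; no inferential procedure is attached
  to role assignment.
* No permutation test is attached to the between-group inertia share.
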