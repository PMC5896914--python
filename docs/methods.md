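# Methods

This note records the statistical conventions, default parameters and
design choices behind `msatnet`, and what the synthetic benchmarks do and
do not demonstrate.

## Data model

Genotypes are diploid, codominant, multiallelic (microsatellite-style);
allele identifiers are integer fragment lengths and are never silently
remapped (dense index remapping happens only inside encoders).  A
genotype with one missing allele is treated as fully missing at that
locus.  GenePop is the interchange format (2- and 3-digit dialects);
because GenePop has no population-name field, the writer records site
names in the title line (`pops=...`) and the reader falls back to the
first individual label per `Pop` block, or to generic `pop_k` labels, when
no such list is present.  Written files group individuals by site, so a
site-grouped table round-trips byte-exactly.

## Diversity statistics

* `He` is Nei's gene diversity (biased form), matching the common survey
  toolchain; the unbiased `2n/(2n-1)` correction is available but off by
  default.
* `F = (He - Ho)/He` is computed **per locus** and then averaged over
  loci (with its standard error over loci); the tabled `F` is therefore
  not the ratio of the tabled means.
* Rarefied allelic richness uses the closed-form hypergeometric
  expectation.  The default rarefaction size is `g = 2 * (smallest number
  of scorable individuals over all site x locus cells)` — the largest `g`
  valid everywhere.  When all sites have equal, complete samples this
  makes `AR` coincide with the raw allele count (the subsample is the
  full sample); the statistic earns its keep exactly when sampling is
  uneven.
* Private alleles are counted within a caller-chosen scope of sites
  (default: all sites in the table) and reported per locus.
* The Hardy–Weinberg exact test conditions on the observed allele counts
  (Levene): the 2n gene copies are randomly re-paired into diploids and
  the p-value is the fraction of pairings whose conditional probability
  is at most the observed one.  Default 10,000 pairings.  The genotypic
  linkage test is a permutation G-test on the genotype x genotype table.
  All permutation p-values use the `(exceedances + 1)/(reps + 1)`
  convention, so p is never 0 and the tests are exact under their nulls.

## Differentiation

AMOVA is computed at the **gene-copy level**: each diploid contributes
two copies, the squared distance between copies is 0/1 (same/different
allele), sums of squares follow the standard among/within decomposition,
variance components are summed over loci, and
`Fst = sigma2_a / (sigma2_a + sigma2_w)`.  This puts the estimate on the
Weir–Cockerham θ scale, which is what the F-model generator's combined
drift parameter predicts; a genotype-level AMOVA (PhiPT-style) was
rejected because it estimates a systematically larger quantity (~+60% on
the study preset) and would not recover the generator's parameter.
Permutations shuffle **individuals** (keeping their two copies together)
across sites — the exchangeable unit under the null.  Negative variance
components are reported but clamped to zero inside Fst, so linearization
never sees negative inputs.

The Fst ceilings answer "how large could a Gst-form Fst possibly be given
what the pooled sample looks like?" for K equal-weight subpopulations:

* **Given M** (pooled frequency of the most common allele), for
  `M >= 1/K` the extremal configuration fixes `floor(K*M)` subpopulations
  on that allele, gives one subpopulation the fractional remainder
  (rest on a single private allele) and fixes every other subpopulation
  on its own private allele; for `M < 1/K` no subpopulation can be fixed
  and the optimum packs private alleles at within-subpopulation frequency
  `K*M`.
* **Given total homozygosity** `J_T = 1 - H_T`: for `J_T <= 1/K` the
  bound is `J_T (K-1)/(1 - J_T)`, exact because pooled homozygosity can
  never fall below `1/K` of the mean within-subpopulation homozygosity
  (all-private configurations attain equality); above `1/K` the bound is
  computed over configurations that fix subpopulations on shared alleles
  with one partially mixed subpopulation interpolating between lattice
  points (where the bound touches 1).

Both ceilings are cross-checked in the test suite against attainment by
explicit extremal configurations and against random-search maximization.
The bounds are steep functions of K; with many subpopulations and highly
polymorphic loci they approach 1, so the two-deme (K = 2) forms are the
informative report for "how much of the theoretical range does an
observed Fst of a few percent actually use".

Geographic distances are haversine great circles with Earth radius
6371 km.  The Mantel test is one-tailed for positive association (the
isolation-by-distance hypothesis), permuting rows/columns of the second
matrix simultaneously; default 999 permutations.

## Individual-level networks

Similarity between individuals i and j at a locus is
`sum_a w_a * min(copies_i(a), copies_j(a))` with `w_a = 1/2` (uniform
allele sharing) or `w_a = (1 - f_a)/2` (rarity-weighted, default;
`f_a` = pooled frequency), averaged over the loci scorable in both.
Both weightings are bounded in [0, 1] and symmetric.

The threshold sweep uses 20 evenly spaced thresholds from 0 to the 90th
percentile of positive edge weights.  Communities are found by weighted
greedy modularity maximisation (Clauset–Newman–Moore, via igraph).  The
community x site association is tested with Fisher's exact test — exact
two-sided hypergeometric for 2x2 tables, otherwise Monte-Carlo with
fixed margins (Patefield sampling; default 100,000 tables, +1 smoothing).
A threshold counts as *tested* only while at least half the individuals
remain connected and at least two communities are found; the overall
null is rejected only when p < alpha at **every** tested threshold.
This all-thresholds rule is deliberately conservative: a single
non-significant scale is enough to withhold the claim that sampling
sites are genetic units.

## Population graphs

Individuals are encoded as multilocus allele-count vectors (one
coordinate per allele, values 0/1/2, the most common pooled allele of
each locus dropped as reference).  Missing genotypes are imputed with
their site's mean vector, contributing nothing to within-site variance.
Within-site genetic variation enters the graph as a **node attribute**
(mean squared distance of members to their site centroid), not as an
edge weight: in the conditional-independence construction the edges carry
covariance-derived lengths, and conflating the two quantities would make
the shortest-path distance meaningless.

The among-site covariance is the Gower double-centering of the squared
centroid-distance matrix.  That matrix is rank K−1 by construction
(centering), so the precision matrix is the Moore–Penrose pseudo-inverse
(rcond 1e-10, condition number logged).  Partial correlations
`rho_ij = -omega_ij / sqrt(omega_ii omega_jj)` feed the edge exclusion
deviance `EED = -n ln(1 - rho^2)` with `n` = total individuals
(configurable), screened against chi-square(1) at per-edge alpha = 0.05
by default, Bonferroni on request.  Retained edges carry length
`sqrt(s_ii + s_jj - 2 s_ij)`, i.e. the centroid distance.

Two derived analyses use different edge screens on purpose:

* **Communities.**  Spectral (leading-eigenvector) modularity with edge
  affinity = the positive part of the among-site **correlation**.  The
  inverse edge length, the naive affinity, has weak contrast (within- vs
  between-community lengths differ by ~40% on the planted benchmark) and
  recovers planted blocks in under half the replicates; the correlation
  affinity recovers them in ~96%.  `affinity="inverse_length"` is kept as
  an option.
* **cGD.**  Shortest-path lengths over retained edges (Dijkstra);
  disconnected pairs are infinite and excluded from Mantel tests with a
  warning.  The screening level trades two failure modes: at per-edge
  alpha = 0.05 the K(K−1)/2 tests admit some spurious long-range edges
  that shortcut the transect (noticeable when differentiation is strong),
  while the Bonferroni screen over-prunes weakly differentiated data and
  can disconnect the graph.  The default (0.05) is the better distance
  backbone at study-scale differentiation.  Under either screen,
  the often-quoted expectation that cGD gives *stronger* IBD signal than
  pairwise linearised Fst does not reproduce under these simulators: over
  stepping-stone replicates the cGD Mantel r is positive and significant
  but on average slightly below the Fst-based r (and clearly below it
  when differentiation is study-scale weak, where pairwise Fst IBD is
  already very clean).  The package therefore asserts only that both
  measures detect IBD, and reports both correlations side by side.

Random-walk betweenness is Newman's current-flow betweenness with edge
conductance 1/length (networkx implementation, cross-checked in the test
suite against per-pair unit-current Laplacian solves to 1e-8): unit
current between every source–target pair, a node scores the net current
through it, normalised by the (n−1)(n−2)/2 pairs that exclude it, hence
scores in [0, 1].  On trees it provably equals geodesic betweenness.  The
per-site report keeps the diversity ranking (Ho, AR) and the RWB ranking
separate; no composite index is invented.

## Synthetic data

The primary generator is a two-level F-model: ancestral frequencies per
locus from a symmetric Dirichlet (concentration 1), community frequencies
Dirichlet-centred on ancestral with concentration `(1-F)/F * p`
(Balding–Nichols), site frequencies likewise within communities, and
genotypes as two independent draws per individual per locus.  The
combined differentiation `F_total = 1 - (1-F_c)(1-F_s)` is the analytic
target for every Fst estimator.  Two presets:

* `study_preset` — 14 sites x 20 diploids, 6 loci x 19 alleles, four
  contiguous community blocks (3, 5, 3, 3) on a north–south line,
  `F_c = F_s = 0.02` (`F_total ~ 0.04`, the magnitude of the motivating
  survey).
* `planted_communities_preset` — same layout with `F_c = 0.1`,
  `F_s = 0.05`: distinct enough basins for community-recovery and
  association benchmarks.

The stepping-stone generator is a forward-time Wright–Fisher chain:
deterministic nearest-neighbour mixing (interior demes `(1-m)` own +
`m/2` per side, end demes `m/2` with their single neighbour) followed by
multinomial resampling of `2 * effective_size` gene copies.  The
`stepping_stone_preset` (14 demes x 20 diploids, m = 0.05, Ne = 500,
200 generations) produces overall differentiation around 0.03 — the
study-scale magnitude — together with a clear isolation-by-distance
gradient; stronger structure is available by lowering m or Ne.

What the generators deliberately **omit**: microsatellite mutation
(stepwise or otherwise), null alleles and allelic dropout, linkage
between loci, within-site inbreeding, selection, and spatial structure
within sites.  Passing benchmarks therefore demonstrates estimator
correctness under drift/migration sampling, not robustness to genotyping
artefacts — the motivating survey handled those upstream (two of its
eight loci were discarded for suspected null alleles before analysis).

## Benchmarks and problem sizes

The test suite checks closed forms against exhaustive or brute-force
oracles at sizes where the oracle is cheap: rarefaction against full
subsample enumeration (up to 12 gene copies), RWB against per-pair
current solves (100 random graphs up to 12 nodes, 1e-8) and geodesic
betweenness on trees, modularity detectors against exhaustive partition
search (up to 8 nodes), Monte-Carlo Fisher against the exact
hypergeometric on 2x2 tables (within 0.005).  Parameter recovery runs
100 study-preset replicates (mean AMOVA Fst within 25% of `F_total`) and
25 planted-preset replicates (ARI >= 0.9 against planted basins in >= 80%).
Type-I calibration uses 500 replicates per test at nominal alpha = 0.05
with a +/-2-point band; the LD null uses 50 diploids at 3-allele loci so
that table discreteness does not dominate (sparser designs make any
exact-style test conservative, which would measure the design rather
than the implementation).

## Known limitations

* The Fst ceilings above the `1/K` homozygosity lattice use a structured
  family of extremal configurations; they are verified against numerical
  maximization on a grid but not proven optimal for every (J_T, K).
* The pseudo-inverse step of the population graph can inflate partial
  correlations when K is small or sites are nearly collinear in allele
  space; the condition number is logged and the Bonferroni screen is the
  remedy when edge lists must be trusted individually.
* AMOVA rescales pairwise information to the full locus count when data
  are missing; under extreme, non-random missingness the components are
  biased.
* Mantel tests exclude non-finite pairs (disconnected cGD); with many
  such pairs the test loses both power and interpretability.
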