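# Methods

## Preprocessing

Genes with counts below the filter threshold (default 10) in **every**
sample are discarded; everything downstream operates on the retained
"expressed" universe.  Normalization is log2 counts-per-million with a prior
count of 0.5 (so zeros map to a finite value), followed by quantile
normalization: each sample's sorted values are replaced by the across-sample
mean of sorted values, ties receiving the mean of the reference values their
ranks span.  The per-gene log2 fold is the unweighted difference of condition
means of the normalized values.  No precision weighting or moderated
statistics are applied: every downstream test consumes only the per-gene
fold, so gene-level variance moderation would not change any definition used
here.

Detection flags are computed from **raw** counts: a gene is detected in a
condition when any replicate reaches the detection threshold (default 10,
deliberately the same constant as the expression filter — "undetected" means
all raw counts are zero, "detected" means at least one count ≥ 10; values in
between make a gene neither switched on nor off).

## Module contrast test

The module statistic is the mean member fold minus the grand mean fold.  The
null is generated by drawing B same-size gene subsets without replacement
from the expressed universe (subsets, not bootstrap resamples: module
membership is a subset hypothesis).  Two-tailed significance folds the
statistic by absolute value, and the estimator (1 + exceedances)/(B + 1)
keeps p strictly positive with floor 1/(B + 1).  Ties at |T_obs| are counted
as exceedances (tolerance 1e-12), so constant folds give p = 1 exactly.  A
module equal to the whole universe has contrast identically zero and is
reported with p = 1 rather than sampled.

Per-module RNG streams are derived by SHA-256 hashing of (master seed, set
id), so p-values do not depend on collection order and any module can be
recomputed in isolation.  The sampler draws index tuples by rejection when
m² ≤ N (collisions are then rare) and falls back to a random-key
argpartition per draw otherwise; both strategies are exact uniform samplers
of m-subsets.

`exact_permutation_pvalue` enumerates all C(N, m) subsets (cap 10⁶) and is
the oracle used by the tests; the observed subset is one of the enumerated
ones, so the exact p is also positive by construction.

## Multiple testing

Module contrast and switch enrichment use Storey–Tibshirani q-values: π₀ is
estimated from π₀(λ) = #{p > λ}/(m(1 − λ)) on λ = 0.05, 0.10, …, 0.95,
smoothed with a cubic least-squares polynomial evaluated at λ = 0.95 and
clamped to (0, 1].  With fewer than 100 tests the smoother is unstable and
π₀ is forced to 1, which reduces to Benjamini–Hochberg and is conservative.
Cluster annotation deliberately uses plain Benjamini–Hochberg within each
cluster's test family instead — the two FDR procedures are kept distinct on
purpose, mirroring how the two analyses are usually reported.

## Switched-on/off enrichment

Switched-on genes are undetected in control and detected after treatment;
switched-off the reverse.  Over-representation of a selection of size n in a
pathway with K genes is the upper hypergeometric tail P(X ≥ k_obs) with
expected overlap nK/N; the background N is always the full expressed
universe, not the selection union.  Only over-representation is tested;
depletion is not reported.

## Gene-set construction

Ontology annotations are propagated along is_a edges (a gene annotated to a
term belongs to every ancestor), collections are restricted to the expressed
universe, sets below 5 genes are dropped (tiny modules make the sampling
null degenerate; the floor is configurable), and entries with identical
member sets are united, names joined with "; ".  Deduplication runs after
restriction so sets identical *on the expressed universe* merge, keeping the
q-value test count honest.

## Network analysis

A subnetwork around seed regulators keeps direct interactants at confidence
strictly above 0.5 whose |log2 fold| exceeds log2(2), sign-matched to the
requested direction (induced/inhibited analyzed separately); nodes beyond
log2(5) carry a "large" flag; the bridge tabulation between DNA-repair
drivers and oncogenes uses confidence > 0.9 and flags any inhibiting edge as
a contradiction of the expected neutral-or-inducing pattern.

MCL runs on the score-weighted adjacency with self-loops equal to each
node's maximum incident score, inflation 2.0, expansion power 2, pruning at
1e-5, convergence when the largest entry change drops below 1e-6 (cap 100
iterations, warning on non-convergence); clusters are the connected
components of the limit matrix's support, which assigns every node.  The
spectral K-means route embeds nodes with the eigenvectors of the k smallest
eigenvalues of the symmetric-normalized Laplacian and runs k-means++ with 10
restarts; it exists because K-means needs coordinates while the input is a
graph.  Node order is sorted before any matrix is built, making both
algorithms invariant to input labeling.

## Thermosensitivity

AT fraction is (A+T)/(A+C+G+T) with N bases excluded from both sides.  The
thermosensitive set is the top decile of the scored collection (ties at the
cut included); the quantile is configurable because published AT-content
classifications do not pin a threshold.  The direction test reports (a) the
exact two-sided binomial at ½ under the minimum-likelihood convention (sum
of outcome probabilities no larger than the observed count's — for 11 of 12
downregulated this is 26/4096 ≈ 0.0063) and (b) a two-sided Mann–Whitney of
member folds against the remaining universe, exact when the smaller group
has ≤ 8 untied values, otherwise normal approximation with tie correction.
Zero folds are dropped with a logged count.

## Cross-dataset comparison

Log2 folds (not linear folds) are correlated stage-by-stage with the
external table over the declared gene list; Pearson r with the two-sided
t-transform p on n − 2 degrees of freedom, plus the least-squares slope.
Genes missing from either side are counted and reported, never imputed.

## Synthetic data

The generator emulates a 3 + 3 bulk RNA-seq design with negative-binomial
counts (var = μ + 0.1 μ², a typical bulk dispersion), baseline log2 means
uniform on (4, 9) so the count filter is genuinely exercised, 5% planted
all-low genes, 20 planted 30-gene modules shifted by δ = 1 log2 unit, 50
switched-on and 30 switched-off genes, a 12 + 12 stochastic-block
interaction graph (within-block edge probability 0.9 and scores above 0.5,
between-block 0.02 and scores below 0.5, plus six high-confidence
neutral-or-inducing bridges between the two blocks), and 500 sequenced genes
whose top AT-content decile (target AT 0.70 vs background 0.50, length
2,000 so realized fractions concentrate within ±0.05) is 90% down-shifted.

Planted roles are *forced*: on-genes draw exact zeros in control and are
re-drawn until detected in treated, low genes are re-drawn until every count
is below the filter threshold, and all remaining genes until detected in
both conditions.  This makes filter and switch recovery exact set equalities
rather than probabilistic events.  What the generator does **not** emulate:
read-level error structure, gene length and GC biases, correlated expression
within real pathways, library-composition artifacts beyond what the planted
shifts induce, and real STRING score semantics.  Passing tests therefore
demonstrate the correctness and calibration of the machinery, not biological
conclusions about real data.

All randomness descends from one master seed through SHA-256-derived
per-component streams (all below 2³¹), so every dataset, p-value and output
table is reproducible bit-for-bit; written edge lists canonicalize endpoint
order so runs in different processes agree byte-for-byte.

## Problem sizes

The packaged checks run the default-scale study at 10,000 genes with 500
modules at B = 20,000 samplings, the null calibration at 5,000 genes with
500 random modules, and enumeration oracles on universes up to 12 genes —
sizes at which the exact oracle remains feasible while the sampling and
clustering behavior matches the larger regime.

## Known limitations

The fold definition omits voom-style precision weights, so genes with very
low counts contribute noisier folds than a weighted fit would allow; the
Storey smoother is a cubic polynomial, not a df-3 smoothing spline, which
can differ in the third decimal of π₀; MCL cluster extraction via support
components can merge overlapping attractor systems; and the hypergeometric
enrichment treats genes as exchangeable, ignoring gene-length or expression-
level selection biases.
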