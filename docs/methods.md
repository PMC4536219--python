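# Methods

This note documents the models and procedures the package implements,
the conventions adopted where the methods literature leaves choices
open, and what the synthetic-data experiments do and do not demonstrate.

## Elements of Metacommunity Structure

### Ordination

Reciprocal averaging is computed non-iteratively as the SVD of the
chi-square-standardised matrix `(P − rcᵀ)/√(rcᵀ)` with `P` the matrix
scaled to sum 1 and `r`, `c` its row/column mass vectors. Row (site) and
column (taxon) scores are principal coordinates (`D_r^{-1/2} U Σ`);
eigenvalues are the squared singular values. This is deterministic up to
the sign of each axis; the sign is fixed so that the first input site
scores non-negatively (ties resolved by the first taxon's score).

Matrix arrangement (`order_matrix`) sorts sites and taxa by the chosen
axis score, stable ties by input position, and canonicalises the
reflection (the lexicographically smaller of the two reversals is
returned). Canonicalisation makes ordering idempotent and independent of
the input row order; it cannot affect any EMS statistic, because
embedded absences, replacements, and boundary dispersion are invariant
under joint reversal of sites and taxa.

Inputs are filtered first: taxa at fewer than two sites are removed
(singletons carry no co-occurrence information and bias coherence and
clumping), then all-empty sites are dropped (ordination is undefined for
zero rows). Sites dropped here remain in the diversity analyses, which
do not need ordination.

### The r1 null ensemble

Null matrices preserve each site's observed richness exactly and draw
that many taxa without replacement with probability proportional to each
taxon's observed incidence. Sampling uses the exponential-race
construction (keys `Exp(1)/w_j`, keep the k smallest), which is
distributionally identical to sequential weighted draws; the test suite
checks the per-taxon occupancy means against an independent sequential
sampler. Per-matrix RNG streams are spawned from one root seed, so the
ensemble is reproducible and could be generated in parallel without
changing results.

Each null matrix is re-ordinated by reciprocal averaging before its
statistics are measured — each null is scored on its own best
arrangement, exactly as the observed matrix is. A
`reordinate_nulls=False` switch scores nulls on the empirical ordering
instead. A null draw can leave a taxon with no occurrences; such columns
are dropped before ordinating that null (they contribute no gaps or
replacements either way), and nulls that cannot support the requested
axis are skipped and counted.

### Statistics and classification

* **Coherence**: embedded absences are counted in both taxon ranges
  (columns) and site ranges (rows) by default (`embedded_mode="both"`;
  `"columns"` restricts to species ranges).
* **Turnover**: ranges are filled column-wise (species ranges made
  contiguous; presences never removed) and replacements are summed over
  unordered taxon pairs as (#sites with i only) × (#sites with j only).
* Both are tested with `z = (null mean − observed)/null SD` and a
  two-tailed normal p. The z sign convention matches the reporting
  convention of the survey literature this package follows: positive z
  for fewer embedded absences than null (coherent), negative z for more
  replacements than null (positive turnover).
* **Boundary clumping**: each taxon contributes its first- and
  last-presence positions; Morisita's index of the per-position counts
  is tested with the Pearson dispersion chi-square (`df = T − 1`),
  evaluated **two-sided** (`p = 2·min(sf, cdf)`), since clumping inflates
  and hyperdispersion deflates the statistic. One-sided evaluation would
  make the evenly-spaced and hyperdispersed-loss structures undetectable.
* **Edge trimming**: positions within 10 % of each end of the ordination
  (at least one position) are excluded from the boundary counts by
  default (`boundary_edge_trim="auto"`). The matrix extent truncates
  every range that reaches it, and noise presences dragged toward the
  score extremes pile range edges onto the outer positions; measured on
  communities generated with uniformly dispersed boundaries, including
  those positions inflates the dispersion chi-square by ≈ +12 on average
  and misclassifies ~40 % of such communities as clumped. Set
  `boundary_edge_trim=0` to count every position.

Classification: non-significant coherence → Random; significant negative
coherence → Checkerboard; otherwise significant turnover splits into the
positive-turnover family (Evenly spaced / Gleasonian / Clementsian as MI
is significantly < 1 / indistinct / significantly > 1) or the nested
family (hyperdispersed / random / clumped species loss); non-significant
turnover yields the quasi variant of the family given by the direction
of its deviation from the null mean (a tie, observed exactly at the null
mean, is assigned to the positive-turnover family). Exhaustive
enumeration reaches exactly 14 labels. α = 0.05 two-tailed throughout,
configurable.

## Diversity

Richness is the per-site count of non-zero taxa. Rarefied richness uses
Hurlbert's hypergeometric expectation at n = 100 individuals, computed
with log-gamma binomials for numerical stability; sites with fewer than
n individuals return observed richness with a warning flag (rarefaction
to a larger sample is undefined). Simpson's index is `1 − Σp²`; empty
sites yield NaN with a warning.

Beta dispersion decomposes the Bray–Curtis matrix (abundance-based) by
classical scaling keeping *all* eigenvalues; distances to the group
centroid subtract the imaginary-axis component,
`d = √(max(d_real² − d_imag², 0))`, the standard correction for
non-Euclidean dissimilarities. Group differences are tested with a
parametric one-way ANOVA F on the distances (not a permutation test),
matching the reporting style of the survey workflow. Tukey HSD comes
from statsmodels; compact letter displays use insert-and-absorb.

## Boosted regression trees

Each stage fits a `DecisionTreeRegressor` with `max_leaf_nodes = 6`
(five splits, grown best-first) to the working residual `y − μ` on a
50 % row subsample, added with shrinkage. Gaussian loss uses the leaf
means directly; Poisson loss (log link, baseline `log ȳ`) replaces each
leaf value with the Newton step `log(Σy/Σμ)` clipped to ±4 for
stability. Deviance conventions: Gaussian = mean squared error; Poisson
= `mean 2[y log(y/μ) − (y − μ)]` with the `y = 0` log term set to zero.

Tree-count selection grows one model per CV fold in lock-step, records
mean held-out deviance every 50 trees, stops after five steps without
improvement (or at `max_trees`), and keeps the minimising count; a
warning suggests a ten-fold smaller learning rate when fewer than 1000
trees are selected. Folds are seeded; for Poisson they are stratified by
response tertile to stabilise small-N section models. Reported metrics:
training and cross-validated percent deviance explained
(`100·(null − residual)/null`, held-out null deviance computed against
the training-fold baseline), CV correlation ± SE, and mean null / CV
residual deviance ± SE.

Relative influence sums each tree's impurity-reduction attribution (the
standard least-squares approximation for the Poisson case as well) over
all stages, normalised to percentages. Predictor assembly drops
catchment size for the section models (the sections are defined by
catchment-size ranges), keeps it for the all-sites model, appends the
two geographic PCoA vectors when spatial predictors are requested, and
can add a two-level drainage factor.

Defaults mirror the field convention (learning rate 0.001, five splits,
bag fraction 0.5, 10 folds); the package's own synthetic checks use a
larger learning rate and smaller tree budgets so the selection curve is
explored at desk scale — this changes run time, not the contracts being
tested.

## Synthetic data

The generator places sites at positions 0..S−1 of a latent gradient and
builds taxon ranges per structure:

* **clementsian** — `n_groups` contiguous equal blocks; taxa assigned
  round-robin occupy their block exactly (shared boundaries).
* **gleasonian** — independent ranges, width uniform on
  `[w̄/2, 3w̄/2]` around a mean width `w̄ = S/4`, start uniform over the
  admissible interval. The design keeps the construction's boundary
  distribution close to uniform (small dispersion-chi-square
  noncentrality) while ranges stay wide enough to carry ordering signal;
  very narrow ranges lose the signal and very wide ranges have so few
  admissible starts that their edges co-occur, both of which masquerade
  as boundary clumping.
* **nested** — ranges share gradient end 0 with widths spanning 2..S.
* **evenly_spaced** — equal widths, equidistant starts.
* **checkerboard** — mutually exclusive species pairs: each pair claims
  a pool of 2k sites (k uniform on [S/8, S/4], pools spread
  least-loaded-first so no site subset is over-used) and splits it into
  complementary halves.
* **random** — i.i.d. Bernoulli(prevalence).

Cells are then flipped with probability `noise_eps` (default symmetric;
a one-sided false-absence-only option mimics survey detection error).
Abundances conditional on presence are zero-truncated negative binomial
(`1 + NB` parameterised so the configured mean is the mean positive
count). The environment table makes **elevation** the driver — an affine
function of the gradient plus Gaussian noise (`env_noise_sd`, gradient
standardised to unit SD) — with land-use and chemistry nuisance columns
sharing correlation `nuisance_corr` with the driver, log-uniform
catchment sizes spanning all three river sections (headwaters < 20 km²,
mid-sized [20, 100) km², large ≥ 100 km²), and planar coordinates whose
x-axis optionally tracks the gradient.

### What the recovery experiments show — and don't

At the study conditions used throughout (40 sites × 50 taxa, 1 % noise,
200 nulls, α = 0.05), the classifier recovers the generating family
reliably for clementsian, nested, gleasonian and random generators
(≳ 80–100 % of seeded replicates). These are clean, single-gradient
communities; real survey data add detection heterogeneity, multiple
interacting gradients and taxonomic aggregation that the generator does
not emulate, so recovery rates here are an upper bound on field
performance, not an estimate of it.

Checkerboard structures are a documented exception: under the r1 null
with re-ordination, a matrix scores as checkerboard only if it holds
*more* embedded absences under its own best arrangement than i.i.d.
null draws do under theirs. Mutually exclusive pairs cannot push far
into that tail — a complementary pair is jointly no gappier than two
independent columns with the same marginals — and the only available
signal (the null's column-total dispersion around the gap-maximising
prevalence) is worth roughly two null standard deviations. Detection
power for the shipped checkerboard generator is therefore ~15–30 %, and
the corresponding recovery check is expected to fail; this mirrors the
low checkerboard sensitivity reported for coherence-based co-occurrence
tests generally.

## Numerical and degenerate-input conventions

* Rank-deficient matrices (fewer non-trivial ordination axes than
  requested) raise a descriptive error; the pipeline skips such
  subset × axis combinations with a warning rather than aborting.
* Score ties in ordering break by input position (stable sort).
* PCoA spatial vectors require positive eigenvalues for the retained
  axes; geographic distances are planar Euclidean (project
  longitude/latitude upstream).
* Section categories are half-open (`[20, 100)`, `[100, ∞)` km²) so the
  partition is deterministic at the printed breakpoints.
* Within-section analyses re-apply the rare-taxon filter by default
  (a taxon at two sites overall may be a singleton within a section);
  `refilter_subsets=False` disables this.
* The pipeline manifest nulls its timing field so reruns with the same
  configuration are byte-identical.

## Problem sizes

Stochastic checks run at desk scale by design: structure recovery at
40 × 50 with 200 nulls and 25 replicates per structure; BRT driver
recovery over 20 seeds at 80 sites; the acceptance script uses the same
recovery conditions, 10 seeds for the BRT rate, and a 1000-null ensemble
for the single-study EMS statistics.
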