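# riverems

Regional analysis of river invertebrate assemblages from site-by-taxon
matrices: **Elements of Metacommunity Structure** (EMS) classification,
alpha/beta diversity comparison across river sections, and
**boosted-regression-tree** (BRT) attribution of composition and richness
to environmental and spatial predictors. A synthetic-data generator with
known idealised structures makes every stage testable end to end.

The methods target benthic-invertebrate survey data (sites spanning
headwaters to large rivers, classified by catchment size), but the
machinery applies to any site-by-taxon incidence table — e.g.
site-by-OTU tables in microbial ecology.

## The analysis

**EMS.** A presence/absence matrix is ordinated by reciprocal averaging
(correspondence analysis), arranging sites and taxa along a latent
gradient. Three statistics are then tested against an ensemble of
fixed-incidence-proportional ("r1") null matrices, each re-ordinated
before scoring:

1. *Coherence* — embedded absences **Abs** (gaps inside taxon and site
   ranges). With null mean μ and SD σ, `z = (μ − Abs)/σ`: significantly
   positive z = coherent, negative = checkerboard, otherwise random.
2. *Species turnover* — replacements
   `Re = Σ_{i<j} (#sites with taxon i only) · (#sites with j only)` on the
   range-filled matrix; observed above the null mean = positive turnover,
   below = nested subsets.
3. *Boundary clumping* — Morisita's index
   `MI = T·Σ nᵢ(nᵢ−1) / (N(N−1))` of range-edge counts over site
   positions, with a two-sided chi-square dispersion test.

Combining the outcomes (with "quasi" variants when turnover is
non-significant) classifies the matrix into one of 14 idealised
structures (Clementsian, Gleasonian, evenly spaced, nested subsets,
checkerboard, random, and their quasi/nested sub-forms).

**Diversity.** Per-site richness, Hurlbert rarefied richness
`E(S_n) = Σᵢ [1 − C(N−Nᵢ, n)/C(N, n)]` (n = 100 individuals), Simpson's
`1 − Σpᵢ²`, and beta dispersion (distance to river-section centroid in
Bray–Curtis PCoA space, keeping imaginary axes), compared across sections
with one-way ANOVA and Tukey HSD.

**BRT.** Stochastic gradient boosting of 5-split regression trees
(learning rate 0.001 by default, bag fraction 0.5), Poisson loss for
richness and Gaussian loss for the primary ordination axis, with
stage-wise 10-fold cross-validated selection of the tree count and
per-variable relative influence (percent of total loss reduction).

## Worked example

```python
import riverems as r

cfg = r.SyntheticConfig(structure="clementsian", n_sites=40, n_taxa=50,
                        noise_eps=0.01, seed=3)
inc, gradient, groups = r.simulate_metacommunity(cfg)
inc = r.filter_rare_taxa(inc)          # drop taxa at < 2 sites
inc, dropped = r.drop_empty_sites(inc)

est = r.MetacommunityStructure(axis=1, n_sim=1000, random_state=1).fit(inc)
print(est.label_)
print(f"coherence z = {est.coherence_.z:.2f}, turnover z = {est.turnover_.z:.2f}, "
      f"MI = {est.clumping_.morisita:.2f}")
```

```
Clementsian
coherence z = 32.08, turnover z = -26.60, MI = 4.49
```

The generator placed taxa in four blocks along the gradient, so the
fitted structure is Clementsian: far fewer embedded absences than the
null (coherence z ≫ 0), far more replacements than the null (turnover
z ≪ 0, i.e. observed above the null mean), and strongly clumped range
boundaries (MI ≫ 1).

The same pipeline runs from the shell on CSV inputs:

```bash
riverems simulate --structure clementsian --n-sites 60 --n-taxa 40 --seed 2 --outdir demo
riverems run-all demo/abundance.csv demo/sites.csv --n-null 1000 --outdir results_demo
```

which writes `table2.csv` (EMS summaries for all sites + three
catchment-size sections × two axes), `diversity.csv`,
`table3.csv`/`influence.csv` (BRT evaluations and relative influences)
and a JSON manifest that makes reruns byte-identical.

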