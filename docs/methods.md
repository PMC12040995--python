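# Methods

This note documents the models and procedures implemented in `ectonet`,
the numerical choices behind them, what the synthetic-data generator does
and does not emulate, and the known limitations.

## Data model

A network is one host species in one region crossed with one parasite
group (fleas or gamasid mites). Rows are individual hosts, columns
parasite species, entries counts of parasite individuals. Hosts carrying
no parasite of the focal group are excluded at construction: every
position index below is undefined for an isolated node, and the analysis
concerns parasitized individuals. A network is retained only if it holds
at least `min_per_sex` (default 20) parasitized females **and** males —
the filter counts parasitized individuals, after the zero-host exclusion.
All-zero parasite columns are dropped. Duplicate (host, parasite) rows in
long-format input are summed, tolerating denormalized exports. Sampling
sites are pooled within (species, region) and retained as metadata only.

## Position indices

With `A_i` row totals, `A_j` column totals, `m` the grand total:

- **Strength** `s_i = Σ_j a_ij / A_j`. Identity `Σ_i s_i = #parasites`
  holds to 1e-9 and is asserted in tests.
- **Nested rank**: rows are ordered by decreasing binary degree, ties by
  decreasing row total, then input order (stable); rank `r ∈ {1..S}` maps
  to `(r−1)/(S−1)`. The ordering is the deterministic O(S log S) "sort"
  flavour of a maximally nested arrangement rather than a nestedness-
  search; the ordering routine is the single point to swap if a search-
  based arrangement is ever preferred.
- **d′**: `d_i = Σ_{a_ij>0} p_ij ln(p_ij/q_j)` with `p_ij = a_ij/A_i`,
  `q_j = A_j/m`, normalized by the real-valued bounds `d_min = 0`,
  `d_max = ln(m/A_i)` and clamped to [0, 1]. This is a relaxation of the
  integer-constrained normalization of the original index. Under the
  column-capped allocation polytope (`c_j ≤ A_j`), `ln(m/A_i)` is an upper
  bound on any achievable divergence (the maximum of the convex objective
  over the polytope sits at a vertex whose value telescopes to
  `ln(m/A_i)`), so the relaxed d′ is a *lower* bound on the integer-
  normalized value; a brute-force enumeration oracle on small matrices
  verifies this direction. Note the relaxation deliberately keeps
  `d_min = 0`: normalizing by an enumerated integer minimum would shrink
  d′ further and is not attempted.
- **Eigenvector centrality** is computed on the one-mode host projection.
  Projection methods: `sum` (default; shared-parasite pair weights
  `Σ_j a_gj + a_hj`), `binary` (shared-species counts), `newman`
  (shared species down-weighted by `1/(n_j − 1)`). The default is a
  configuration knob because the weighting actually used upstream of the
  published index is not fixed by its definition. Centrality uses power
  iteration (tolerance 1e-12, ≤ 10,000 iterations, uniform start) on
  `I + W` rather than `W`: a bipartite-structured projection (e.g. a path)
  has a symmetric spectrum and plain power iteration oscillates; the shift
  leaves eigenvectors unchanged while making the leading eigenvalue
  strictly dominant. Entries are max-normalized; on a disconnected graph,
  components not carrying the principal eigenvalue decay toward 0.

## Network structure and the null model

- **NODF** (binary): for each unordered row pair, the pair scores
  `100·|shared|/fill_smaller` when the fills strictly decrease, else 0;
  likewise over columns; NODF is the mean over all row and column pairs.
  Equal fills score 0, making the index invariant to row/column
  permutation. The weighted NODF variant is out of scope. Agreement with
  `vegan::nestednodf(order = TRUE)` is checked in the test suite when an R
  installation is present.
- **H2′**: `H2 = −Σ (a_ij/m) ln(a_ij/m)` over filled cells;
  `H2max` is the independence entropy of the marginals; `H2min` comes from
  greedy packing (repeatedly place `min(largest remaining row, largest
  remaining column)` into one cell). `H2′ = (H2max − H2)/(H2max − H2min)`
  clamped to [0, 1]. The greedy minimum is a heuristic: a real matrix can
  occasionally be more concentrated than the greedy packing, in which case
  the clamp absorbs the overshoot (a small positive bias in H2′). Bounds
  and endpoint cases are tested; an exact integer-programming minimum is
  not attempted.
- **Null model**: draws preserve the grand total `m` and the fill `L`
  exactly, with cell probabilities proportional to `A_i·A_j`. Phase 1
  guarantees coverage — cells are sampled by `P` and accepted while they
  cover a still-empty row or column (at most rows+cols−1 acceptances; if a
  tightly filled matrix makes the greedy coverage overshoot `L`, the draw
  restarts) — then the remaining `L − |selected|` cells are drawn by `P`
  without replacement. Phase 2 distributes the `m − L` remaining
  interaction events over the selected cells by `P` with replacement, on
  top of the guaranteed 1 per cell. The resulting marginals are
  *approximately* proportional to the observed ones — the coverage
  constraint shifts expected totals by a few percent, which is intrinsic
  to this null-model family, so tests check tracking within 3 per-draw
  SDs and near-perfect correlation rather than exact unbiasedness.
- **Z-scores** use the null sample mean and the (n−1) standard deviation;
  a zero-variance ensemble yields Z = 0 with a warning. Defaults: 1000
  null matrices per network; every stochastic operation takes an explicit
  seed and logs it.

## Modules and roles

Barber's bipartite modularity
`Q = (1/m) Σ_ij (a_ij − A_i A_j/m) δ(g_i, h_j)` is maximized by weighted
label propagation: rows start with unique random labels, columns adopt
their best row label, and both sides then alternately adopt the label
maximizing their contribution until Q stops improving, followed by a
greedy module-merge phase that accepts any merge with non-negative gain
(so a structureless network collapses to one module). Ten seeded restarts
are run and the best Q kept; simulated-annealing optimization is not
implemented — on planted two-block benchmarks (within-block density 0.8,
between 0.05) label propagation recovers the partition with adjusted Rand
1 in ≥ 95% of runs.

`z` and `c` use binary degrees by default (a weighted variant sits behind
a flag): `z_i` standardizes the within-own-module degree over the hosts of
that module (0 when the module sd is 0) and `c_i = 1 − Σ_t (k_it/k_i)²`.
Role thresholds are the per-network empirical 95th percentiles of z and c
(linear interpolation between order statistics — percentile conventions
differ, so the definition is fixed here), pooled over both sexes within
the network; "high" means strictly greater, so ties at the threshold are
"low" and an all-equal network is all-peripheral. The classic universal
cutoffs (z = 2.5, c = 0.62) are available as an option, not the default.

## Within-network sex tests

- Parasite counts: NB2 negative-binomial regression (log link, ML
  dispersion), Wald z for the male-vs-female coefficient. Richness:
  Poisson GLM. Wald rather than likelihood-ratio inference is used
  throughout so a single z per test is reported.
- **db-MANOVA**: index columns are centred and scaled to unit variance by
  default (strength is unbounded while the other three live in [0, 1];
  the choice is toggleable for sensitivity analysis), Euclidean
  ("Pythagorean") distances are formed, and the one-way pseudo-F is
  `((SST − SSW)/(g−1)) / (SSW/(N−g))` with `SST = (1/N) Σ_{i<j} d²`,
  `SSW = Σ_g (1/n_g) Σ_{i<j∈g} d²`. On univariate input this equals the
  classical one-way F exactly (asserted to 1e-10, and against an
  independent PERMANOVA implementation).
- Permutation p-values use full randomization of sex labels and the
  `(1 + #{F* ≥ F_obs})/(1 + nperm)` convention (never 0, exact on the
  permutation grid); for this one-factor design full randomization
  coincides with residual randomization under the intercept-only reduced
  model. Default 10,000 permutations. No multiplicity adjustment is
  applied anywhere, deliberately.

## Across-network comparative models

- Sex-difference predictors: `ln(max(mean_M/mean_F, mean_F/mean_M))` per
  index (dNR, dSS, dEC, dDP), which is ≥ 0 and symmetric; non-positive
  means raise an error with a suggested index offset.
- **PGLS**: `y ~ N(Xβ, σ²C)` with `C` the shared-branch-length Brownian
  covariance of the host tree. Responses default to the Z-standardized
  NODF/H2′ (networks differ in size and fill, so raw indices are not
  comparable across species; raw responses remain selectable). Branch
  lengths can be reset to 1 (`unit_branches`), and a species sampled in
  two regions is expanded into a unit-length cherry of sister tips before
  the covariance is computed. Estimation is ML: `β̂ = (XᵀC⁻¹X)⁻¹XᵀC⁻¹y`
  via Cholesky whitening, `σ̂² = RSS/n` for the likelihood and
  `AIC = −2ℓ + 2(p+2)` (all coefficients plus σ²); coefficient standard
  errors use the unbiased `RSS/(n−k)` so t-tests match standard GLS
  output. R² compares GLS residual to GLS intercept-only sums of squares;
  the overall F tests all slopes jointly. Pagel's λ is not optimized —
  plain Brownian motion only. All 2⁴ predictor subsets (including
  intercept-only) are fitted and ranked by AIC; ties break toward fewer
  predictors, then lexicographically. ML (not REML) keeps AICs comparable
  across fixed-effect structures.
- **Beta GLMM** on role proportions: responses are shifted off the
  boundary by exactly ±1e-7, modelled as Beta(μφ, (1−μ)φ) with logit mean
  link, constant precision φ, and a Gaussian species random intercept.
  The marginal likelihood integrates the intercepts by a Laplace
  approximation (vectorized damped Newton for the per-group posterior
  modes); adaptive Gauss–Hermite quadrature (`n_agh ≥ 5`) is available as
  a cross-check and agrees with Laplace to ~0.05 on the sex coefficient in
  simulations. log φ is softly bounded at 12 so near-constant proportions
  cannot drive the precision to numerical infinity. If the random-
  intercept variance collapses below 1e-4 the model refits as fixed-
  effects beta regression and is flagged `collapsed`. Models are fitted
  per parasite group, both per role (proportion ~ sex) and pooled over
  roles with a role fixed effect; neither variant is treated as the
  canonical one.

## Synthetic data generator

The generator emulates a field survey: per host, total parasite load is
negative-binomial (gamma-shape `nb_dispersion`, default 1 — strongly
overdispersed, as ectoparasite counts are; mean `nb_mean` = 8, multiplied
by `male_abundance_mult` for males), conditioned on ≥ 1 by redraw so each
network holds exactly `hosts_per_sex` (default 25) parasitized hosts per
sex. Loads are allocated over parasite species by a multinomial whose
probabilities follow a geometric rank-abundance curve (ratio 0.75 — a
few common and many rare species, which keeps nestedness non-trivial),
perturbed per sex by a Dirichlet draw with concentration `base/shift`
(`male_composition_shift = 0` means identical sex compositions). The
load/allocation split makes abundance and composition effects separately
controllable, unlike independent per-species negative binomials. A
pure-birth (Yule) tree is simulated over species and the per-species true
effects are written next to the data.

What it does **not** emulate: spatial or temporal structure within a
region, host heterogeneity beyond sex (age, body mass), parasite
interactions within hosts, aggregation of parasites across hosts beyond
what the NB load induces, and imperfect detection. Passing calibration
and recovery tests therefore show the *statistical machinery* is correct
under the stated generating process, not that field data meet its
assumptions.

## Problem sizes and defaults

Pipeline defaults mirror the study design the package implements: ≥ 20
parasitized hosts per sex, 1000 null matrices, 10,000 permutations, 95th
percentile role thresholds. The test suite and the acceptance script
exercise the machinery at sizes chosen to make Monte-Carlo error small
relative to each check's tolerance while keeping a complete run in the
minutes range: permutation-test calibration uses 1000 null replicates at
999 permutations; power monotonicity 150 replicates per abundance
multiplier at 199 permutations; negative-binomial recovery 200 replicates
at 200 hosts per sex; PGLS recovery 500 Brownian replicates on a 100-tip
Yule tree; beta-GLMM recovery 200 replicates of 20 species × 2 sexes; the
packaged end-to-end collection is 21 species × 1 region × 2 parasite
groups (42 networks) at 200 nulls and 999 permutations.

## Known limitations

- The nested-rank ordering is the degree-sort arrangement, not a
  nestedness-maximizing search; on matrices with many degree ties the two
  can differ.
- H2min (greedy) and the d′ normalization are approximations with known,
  bounded bias directions (H2′ slightly high, d′ slightly low).
- The null model's marginals are approximately, not exactly,
  proportional to the observed ones; Z-scores inherit that approximation.
- PGLS assumes plain Brownian residuals; no λ/OU transformations, no
  measurement-error model.
- The beta GLMM integrates a single random intercept; crossed or nested
  random effects are not supported.
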