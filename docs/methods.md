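# Methods

This note records the statistical models the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices made where more than one
reasonable option existed.

## Survey-weighted regression engine (`design_glm`)

The engine fits Gaussian linear models by weighted least squares,
β̂ = (X'WX)⁻¹X'Wy, under a stratified two-stage design: subjects carry a
stratum label, a primary sampling unit (PSU) label nested in the stratum,
and a positive sampling weight. The coefficient covariance is the
Taylor-linearization (sandwich) estimator: per-subject weighted scores
uᵢ = wᵢxᵢ(yᵢ − xᵢ'β̂) are summed to PSU totals, centered within each
stratum, scaled by n_h/(n_h − 1) over the stratum's n_h PSUs, and the summed
outer products are pre/post-multiplied by (X'WX)⁻¹. Design degrees of
freedom are (#PSUs − #strata). No finite-population correction is applied
(sampling fractions are treated as negligible).

The multivariate Wald test of a coefficient subset S refers
(β_S'V_S⁻¹β_S)/q to F(q, df − q + 1) with q = |S|. The df convention
df₂ = design df − q + 1 is the standard design-based choice; for q = 1 it
reduces to the squared t statistic on the design df.

Deliberate hard errors, rather than silent fixes: strata with a single PSU
(the variance contribution is undefined; synthetic designs can always
provide ≥ 2), rank-deficient model matrices (reported with the offending
column names), and numerically singular Wald submatrices. Only a Gaussian
engine is provided: metabolites are always the outcome and are
rank-normalized, so binary sleep phenotypes enter as 0/1 *predictors* and no
logistic machinery is needed.

A practical constraint worth stating: the sandwich estimator needs more
PSUs than regression parameters. Model 1 expands to ~13 columns after
dummy-coding, so the generator's default design uses 8 strata × 6 PSUs
(design df 40); analyses on designs with only a dozen PSUs will have
unstable variance estimates, which is a property of the method, not a bug.

## Metabolite preprocessing (`preprocess`)

Order of operations: (1) drop metabolites missing in more than 75%
(strictly) of either batch; (2) half-minimum imputation of xenobiotics
within batch (missingness is treated as left-censoring at the detection
limit, so the fill is 0.5 × the batch minimum observed value);
(3) fully conditional multiple imputation of the remaining metabolites,
separately per batch, producing m completed datasets; (4) rank-based
inverse-normal transform of every metabolite within each batch of each
completed dataset; (5) aggregation pairing the i-th completion of each
batch. Feeding already-processed (rank-normalized, hence negative) data back
in raises — the pipeline is intentionally not idempotent.

The imputation sampler is written in-package so that seeding, sweep count
and donor-pool size are explicit. Each sweep visits every variable with
missing values and performs *proper* predictive mean matching: the linear
model of the variable on all other metabolites plus the configured
covariates is fit on observed rows; (σ², β*) are drawn from their
approximate posterior (scaled inverse-χ² and normal); missing rows are
predicted with β*, observed rows with β̂; each missing value is replaced by
the observed value of a random donor among the k nearest predictions. Every
imputed value therefore lies in the observed support of its variable.
Defaults m = 5, 10 sweeps, k = 5; the m completions use independent streams
spawned from one seed and are bit-reproducible.

Two choices the upstream literature leaves open, fixed here: the
rank-normal offset is Blom's c = 3/8 (configurable), mapping rank r of n to
Φ⁻¹((r − 3/8)/(n + 1/4)), with average ranks for ties; and the imputation
covariates are passed by configuration rather than hard-coded. On the
latter: Rubin-pooled estimates are only unbiased when the imputation model
contains the analysis exposure (congeniality). The recovery tests pass the
phenotype through the covariate configuration; omitting it attenuates a
planted slope by roughly the missing fraction.

## Association scan (`association`)

One record per (phenotype, metabolite, model). Linear and binary phenotypes:
the metabolite is regressed on the phenotype plus the model covariates in
each completed dataset; the m coefficients are pooled by Rubin's rules
(W̄ = mean within-imputation variance, B = between-imputation variance,
T = W̄ + (1 + 1/m)B) with a Barnard–Rubin adjusted t reference capped at the
design df. Xenobiotic metabolites are identical across completions and take
the single-imputation path.

Circular phenotypes: clock time t maps to θ = 2πt/24 (midnight = 0; the
half-open convention [0, 2π)), and sin θ, cos θ enter jointly; each
completed dataset yields a 2-df Wald p-value, and the m p-values are
combined with the aggregated Cauchy association test with equal weights.
ACAT is used because the sine/cosine coefficient covariance has no Rubin
pooling rule, and the Cauchy combination is insensitive to the dependence
among the m tests. The test is invariant to the choice of time origin, since
rotating the circle is a nonsingular linear map of the (sin, cos) pair.

ACAT numerics: p-values are clamped to [1e-15, 1 − 1e-15]; below the clamp
the tangent is replaced by its asymptote 1/(pπ). The tangent itself is
computed as cot(pπ) (reflected for p > ½, where 1 − p is exact in floating
point) and the inverse map as arctan(1/T)/π for T > 0 — both to avoid the
catastrophic cancellation that the naive formulas suffer at extreme
p-values; agreement with a 50-digit reference evaluation is at machine
precision across 10⁴ random inputs.

Benjamini–Hochberg adjustment is applied within each phenotype, pooling all
metabolites and both covariate models (a per-model grouping is available
behind a flag). Significance is an FDR-adjusted p < 0.05 under Model 1 only;
Model 2 records carry adjusted p-values but no flags. Sex-stratified (or any
subgroup) analyses rerun the identical machinery on the subset, with the
design subset accordingly and constant covariates (e.g. sex within a sex
subgroup) dropped from the model matrix.

## Atlas summaries (`atlas_summary`) and network (`bipartite_network`)

Significance sets per phenotype, with domain sets as unions over their
phenotypes. Summaries: counts and percentages of significant metabolites per
phenotype with domain medians/ranges; the top ⌈fraction × n_connected⌉
metabolites by number of distinct phenotype associations (lexicographic tie
break for reproducibility); Dice similarity DSC = 2|X∩Y|/(|X|+|Y|) between
any two sets — an error for two empty sets (0/0), zero when exactly one is
empty.

The bipartite network links phenotypes (rows) to metabolites (columns) where
the Model 1 association is significant; consolidation to domain ×
sub/superpathway sums the association counts into cell weights and takes
their indicator as the binary incidence, pruning empty rows/columns. Total
weight is conserved through consolidation. Metrics:

- connectance-style cluster coefficient L/(R×C) and links per node L/(R+C);
- mean shared partners over row pairs and column pairs;
- **NODF** nestedness (0–100): for each node pair with strictly decreasing
  marginal totals, the percentage of the sparser node's links contained in
  the busier node's, averaged over all row and column pairs. It is reported
  both as NODF (100 = perfectly nested) and in the reversed orientation
  100 − NODF (0 = highly nested). The ecology toolkits offer several
  nestedness algorithms (e.g. matrix-temperature variants); NODF was chosen
  here because it is fully specified, deterministic and oracle-checkable by
  pair enumeration.
- **weighted nestedness** in [0, 1]: the same pair logic on the weight
  matrix, crediting a pair only where the busier node's marginal is strictly
  larger and its cell weights strictly dominate the sparser node's occupied
  cells; rank-based, hence scale-invariant; 1 for a strict weight staircase,
  0 for a constant matrix.
- **Barber bipartite modularity** Q = (1/W)Σᵢⱼ(Aᵢⱼ − kᵢdⱼ/W)[g(i) = g(j)],
  maximized by seeded label switching (alternating best-module moves for
  rows and columns) with an agglomerative module-merge escape and random
  restarts; the single-module start guarantees Q ≥ 0. On all networks with
  ≤ 7 nodes the heuristic matches exhaustive partition search.
- the Fruchterman–Reingold layout for visualization coordinates, delegated
  to networkx's spring layout (repulsion k²/d, attraction d²/k, linear
  cooling) and deterministic given a seed.

## Synthetic cohorts (`synthetic_cohort`)

The generator emulates the statistical structure the analysis assumes:
a stratified design (default 8 strata × 6 PSUs) with Uniform(0.5, 4)
weights, optionally tilted by exp(slope·z_age) to make them informative; two
batches with configurable covariate shifts (e.g. an older batch 2);
demographic/lifestyle covariates with invented but realistic distributions
(only their correlation structure with missingness and phenotypes matters
for testing); phenotypes per domain on all three scales, circular ones drawn
from a von Mises distribution on the 24 h circle (concentration 0 = uniform);
and metabolites built as standard-normal latents plus planted effects,
exponentiated to a positive abundance scale, then censored (xenobiotics:
below the pooled detection-limit quantile) or MAR-masked (logistic dropout
in standardized BMI, intercept calibrated so the realized rate matches the
requested one). Planted effects are linear slopes in SD units per
standardized exposure, or sinusoids amplitude·cos(θ − acrophase) for
circular exposures. An optional common factor induces between-phenotype
correlation; no default correlation is claimed.

Not emulated: LC-MS spectra, retention times, platform drift within batch,
real covariate distributions, or the dependence structure of any specific
study's phenotype panel. Passing tests therefore demonstrate correctness of
the statistical machinery under the stated generating model, not performance
on any particular real dataset.

## Problem sizes and reproducibility

The test-suite and acceptance-script simulations run at deliberately modest
sizes chosen to make Monte-Carlo conclusions stable: 2000 replicates for the
Wald type-I band, 500 scans (n = 500, m = 3, ~10% MAR) for the circular null
KS check, 100 replicates at n = 1500 for power at amplitude 0.4 SD, and 50
atlases (n = 300, 5 phenotypes × 30 metabolites, 10% planted, m = 2) for
end-to-end FDR control. All randomness flows from explicit seeds through
`numpy.random.SeedSequence` substreams; the whole pipeline is bit-reproducible
under a fixed seed, and the CLI derives independent per-stage substreams from
one run seed so stages can be re-run in isolation.

## Known limitations

- The Gaussian-only engine cannot model binary outcomes; this is by design
  (metabolites are the outcomes) but precludes reusing the engine for, e.g.,
  phenotype-as-outcome analyses.
- PMM's posterior draw uses the standard large-sample approximation; with
  very small batches (tens of subjects) Rubin intervals can still be
  slightly anti-conservative.
- The modularity heuristic is exact on small networks but, like all local
  search, carries no global guarantee at scale beyond its restarts.
- NODF and the weighted variant are one specific operationalization of
  nestedness; other toolkits' "nestedness temperature" will differ
  numerically while agreeing in orientation.
- DSC between two empty significance sets is undefined and raised as an
  error rather than assigned a value.
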