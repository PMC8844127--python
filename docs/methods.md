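# Methods notes

## Demography

**Likelihood.** Deaths are recorded at scheduled transfers, so a death is
only known to lie in `[s_k, e_k)`. The Gompertz–Makeham fit maximizes the
exact interval-censored log-likelihood
`sum_k d_k ln[S(s_k) - S(e_k)] + sum_c ln S(t_c)` rather than imputing
midpoint death times; with 2-day windows midpoint imputation biases `beta`
noticeably at the oldest ages, while the interval likelihood does not.
Censored flies (not produced by the generator, but supported on ingestion)
are attached at the interval end, i.e. treated as known alive through the
window in which they left observation.

**Parameterization and optimization.** The optimizer works in
`(ln alpha, ln beta, ln M)` with box bounds, which keeps all three rates
positive and removes the severe scale imbalance between `alpha` (~1e-5/day)
and `beta` (~0.15/day). Initialization: `(ln alpha, beta)` from least squares
of log empirical interval hazard on age, `M` at half the earliest-interval
hazard, plus three fixed jitters of that start (4 starts total, L-BFGS-B,
ftol 1e-9). Non-convergence is reported via `converged_` rather than being
silently accepted; fits with fewer than 10 deaths are flagged unreliable with
a warning. `include_makeham=False` fixes `M = 0`; this pure-Gompertz variant
feeds the Strehler–Mildvan and lifespan-variance diagnostics, which are
phrased in terms of `alpha` and `beta` only.

**Survival summaries.** Event times use the interval-end convention (the
transfer day on which a death is discovered), for both the KM estimator and
the log-rank test. The restricted mean is the exact area under the KM step
function up to `tau` (default: last observed time); its SE uses the
Greenwood-based area formula `Var = sum_j A_j^2 d_j / (n_j(n_j - d_j))`,
dropping terms where the risk set is exhausted. Whether published
mean-lifespan SEs in comparable studies are KM-based or plain SEMs is usually
unstated; for complete data the two agree to within a factor
`sqrt((n-1)/n)`, and this package reports the KM/Greenwood version.

**Mid-age hazards.** Day-45 and day-60 hazards are evaluated from the fitted
GM model, not from empirical bins: at those ages the model-based estimate is
stable while the binned estimate has few deaths per window. A
likelihood-ratio comparison of GM vs pure Gompertz is available via
`gm_interval_loglik`, but no automatic model selection is performed.

## Synthetic-data generator

**Death times** are exact draws from the GM law: the Gompertz component by
closed-form inverse CDF `T = (1/beta) ln(1 - (beta/alpha) ln U)`, the Makeham
component as a competing exponential with rate `M`; the minimum of the two
has exactly the GM hazard. No numerical root-finding is involved, so the
sampler cannot drift from the law it claims to draw from.

**Population.** `(ln alpha, beta)` pairs come from a bivariate normal with
mean at the midpoints and SD at a quarter of the configured ranges, and
correlation `sm_coupling` (default −0.8). Defaults
(`ln alpha` in [−16.5, −6.5], `beta` in [0.11, 0.19], `M = 5e-4`) were chosen
so a 20-genotype panel typically spans short-lived (<50 d) through long-lived
(>65 d) cohorts. The ranges must be wider than the extremes reported for
real inbred fly panels because a strong negative `ln alpha`–`beta`
correlation makes the two parameters' lifespan effects largely cancel along
the correlation axis: variation in lifespan comes mostly from scatter
*around* the Strehler–Mildvan line, so matching the printed parameter
extremes alone would produce an implausibly narrow lifespan range.

**Metabolome.** Signals are planted on a latent log scale and exponentiated
around metabolite-specific baselines (log-normal intensities), so the
standard preprocessing recovers them. Effect classes follow the observed
proportions (33.3% age-increase, 35.6% age-decrease, 93.1% genotype, 42.5%
interaction); the clock set (default 60 of 87) is drawn from the
age-affected metabolites, whose trends are linear in age. Effect sizes are
generator parameters, not literature values — the study design being
emulated reports class proportions, not magnitudes. Defaults
(`age_amplitude 1.2`, `genotype_sd 0.8`, `interaction_sd 1.0`,
`noise_sd 0.5`, all in latent log units) were calibrated once by pilot
simulation to give roughly 80–95% per-term power at BH FDR 0.01 under the
default replicate design (5 genotypes x 4 replicates, 5 x 2, 10 x 1 per
age). Genotypes stop contributing samples at ages > 45 d once their GM
survival drops below 5%, reproducing the unbalanced late-age design of
longitudinal cohorts.

**Lifespan–clock coupling.** With `aa_coupling = c`, samples at the two
oldest ages ≤ 45 d are shifted along the planted per-day clock direction by
`c * (reference_lifespan - genotype_lifespan)` days, i.e. a short-lived
genotype's mid-life metabolome looks `c` days older per day of lifespan
deficit. Early ages are never shifted, matching the empirical pattern that
young-age profiles carry little lifespan signal. The reference lifespan
defaults to the panel median.

**What the generator does not emulate:** batch/block variance components
(columns exist but carry no planted effect — the nuisance screen that would
estimate them is out of scope), non-monotone metabolite trajectories,
heteroskedastic or heavy-tailed measurement noise, and correlated metabolite
modules. Passing tests therefore demonstrate correct recovery of the assumed
structure, not robustness to real-data pathologies beyond it.

## Metabolome statistics

Preprocessing is natural log, a robust QC screen (drop a sample when the
fraction of metabolites with |robust z| > 4 — median/MAD across samples —
exceeds `qc_threshold`, default 1/3), then per-sample centering/scaling
(SD with ddof=1, matching R's `scale`). Row standardization is idempotent,
which the tests assert.

The age x genotype model treats age as categorical and is fitted to all
metabolites at once via QR projections of the four nested designs (the
design matrix is shared across metabolites); F-tests are type II with the
full-model MSE, which equals the per-metabolite OLS ANOVA to 1e-10 on
balanced designs (tested against statsmodels). Direction labels for
age-significant metabolites use the sign of the numeric-age OLS slope. By
default only ages at which ≥ 80% of genotypes are present enter this model,
excluding the unbalanced late ages; PCA and the clock use all samples.
BH-FDR is applied within each term family across metabolites, and within
each (parameter, age) family for the demography associations — the family
structure of the association tables. Association models regress genotype-mean
levels (replicates averaged) on each demographic parameter: demography is a
genotype-level quantity, and replicate-level rows would pseudo-replicate.
Both the linear-model p and Spearman's rho are emitted; q-values follow the
linear-model p.

## Clock

The penalty is implemented exactly as written above — `lambda2` multiplies
the mixed penalty with `(1-lambda1)||b||^2/2 + lambda1||b||_1` — with no
rescaling to other conventions; the intercept is never penalized. Features
enter as-is (rows are already standardized); no per-feature standardization
is applied inside the fit, and there is deliberately no flag for it so the
fitted coefficients remain in days per normalized unit. `lambda1 = 0` uses
the closed-form ridge solution; `lambda2 = 0` uses OLS; the mixed case uses
coordinate descent, validated in tests against an independent
proximal-gradient solver to 1e-6 in objective.

The default tuning grids are `lambda1 in {0, 0.1, ..., 1.0}` and `lambda2`
at 100 evenly spaced values in [1e-6, 1] plus 1000 in [1, 1000] (linear, as
specified, not logarithmic), with 100 repeats of 80/20 splits and 5-fold CV.
That exhaustive grid is expensive (millions of fits), so the pipeline's
*run* configuration defaults to a coarse subgrid (lambda1 in {0, 0.5, 1},
29 lambda2 values, 20 repeats) — the package's own choice of working size;
the full grids remain the dataclass defaults and are available through the
YAML config. Ridge is evaluated along the whole lambda2 path per fold from
one eigendecomposition; other mixing values warm-start coordinate descent
down the path. CV folds are unstratified and all splits derive from the
single seed.

"Consensus" hyperparameters for LOOCV are the grid pair minimizing the mean
CV error across repeats (the per-repeat selections are also reported in
`clock_eval.csv`). LOOCV refits n times at the consensus pair — no hat-matrix
shortcut, because the 1/2N loss scaling makes the effective penalty depend
on n, so the classic leave-one-out identity is not exact here. Hyperparameter
selection and LOOCV both run on the post-QC sample set.

## Numerical choices and degenerate inputs

- `gm_survival` uses the `beta = 0` exponential branch below 1e-12 and
  tolerates overflow in `exp(beta x)` (survival underflows to 0 exactly).
- `fit_gm` requires deaths in ≥ 2 distinct intervals; all-in-one-interval
  tables are rejected (the slope is unidentifiable).
- Exponential-hazard data drive `ln beta` to its lower bound; callers see a
  near-zero `beta_` rather than a failure.
- Constant metabolites or constant theta vectors yield missing associations
  with a warning, never a crash.
- Spearman p-values: exact permutation enumeration below n = 10, the
  t-approximation otherwise.
- Ties in ranks are average-assigned throughout.

## Problem sizes used in tests and the acceptance script

Tests and `scripts/acceptance.py` run the default study conditions
(20 genotypes x 125 flies, 87 metabolites, ~185 samples) with the coarse
tuning grid, 20 tuning repeats, 50 recovery cohorts of n = 1000 per
parameter set, 20 seeds per age-acceleration arm, and 200 null matrices of
30 metabolites for FDR calibration — sizes at which every recovery property
is stable across seeds while a full run stays around a minute.

## Known limitations

- The Makeham term is always fitted strictly positive (log-parameterized);
  data truly generated with `M = 0` return a tiny positive `M` rather than a
  boundary zero. Use `include_makeham=False` for the pure Gompertz model.
- The interval-censored likelihood assumes the observation grid is exact;
  irregular or missed transfers are handled only insofar as the intervals in
  the table reflect them.
- The two-way metabolite model requires a full-rank age x genotype design;
  designs with empty cells fall back to the additive model for the main
  effects and report the interaction as missing.
- `lifespan ~ ln alpha + beta` is fitted by OLS across genotypes and ignores
  estimation error in the fitted GM parameters (as is conventional).
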