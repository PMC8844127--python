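# metaclock

Genotype-resolved aging analysis for cohort studies: Gompertz–Makeham
demography from interval-censored death tables, age-specific functional
phenotypes, per-metabolite statistics, and a penalized-regression
**metabolome aging clock** whose residuals (age acceleration) are tested as
predictors of lifespan and mortality risk.

The package is aimed at experimental-aging labs working with
genotype-replicated cohorts (e.g., inbred *Drosophila* panels such as the
DGRP), where whole cohorts of genetically identical females are followed to
death on a fixed transfer schedule while sibling samples are profiled by
targeted LC-MS at a series of ages. Because every observation of death is a
transfer-day count, all demographic estimation here is interval-censored by
construction.

## The models

**Mortality.** Each genotype's hazard follows the Gompertz–Makeham law

```
mu(x) = alpha * exp(beta * x) + M
```

with baseline (intrinsic) mortality `alpha`, exponential rate of aging
`beta`, and age-independent extrinsic mortality `M >= 0`. Parameters are
estimated by maximizing the exact interval-censored likelihood
`sum_k d_k * ln[S(s_k) - S(e_k)]` over `(ln alpha, ln beta, ln M)`, where
`S(x) = exp(-Mx - (alpha/beta)(e^{beta x} - 1))`. Mean lifespan is the
Kaplan–Meier restricted mean with a Greenwood-based standard error; cohorts
are compared by the k-sample log-rank test. Cross-genotype diagnostics
include the Strehler–Mildvan correlation (Spearman's rho of `ln alpha` vs
`beta`) and the OLS model `lifespan ~ ln alpha + beta`.

**Metabolome.** After log transform and per-sample standardization, each
metabolite is fitted with `level = mu + Age + Genotype + Age x Genotype + eps`
(age categorical; BH-FDR within each term family), levels and age-trajectory
slopes are regressed on the demographic parameters, and PCA summarizes the
global age structure.

**Clock.** Ages are predicted from metabolite profiles by elastic net:

```
min over (b0, b) of  (1/2N) sum_i (y_i - b0 - x_i' b)^2
                     + lambda2 [ (1 - lambda1) ||b||_2^2 / 2 + lambda1 ||b||_1 ]
```

`(lambda1, lambda2)` are tuned by 5-fold CV inside repeated 80/20 splits;
per-sample predicted ages come from leave-one-out CV at the consensus pair.
Age acceleration `theta = predicted - chronological age` is averaged per
genotype and associated with mean lifespan, `ln alpha`, `beta`, and
model-based mid-age hazards.

A synthetic-data generator reproduces the assumed statistical structure
(20 genotypes x ~125 females observed every 2 days; metabolome sampling at
days 4/10/24/45/69/80 with a mixed replicate design; planted age, genotype,
interaction, and clock effects with truth labels), so the entire pipeline
runs and is tested without any external data.

## Worked example

```python
import numpy as np
import metaclock as mc

spec = mc.GenotypeSpec("Ral-like", alpha=np.exp(-11.5), beta=0.115, makeham=5e-4)
deaths = mc.simulate_gm_deaths(spec, observe_interval=2.0, seed=42)
fit = mc.fit_gm(deaths)
mean, se = mc.km_restricted_mean(deaths)
print(f"deaths recorded : {deaths.total_deaths}")
print(f"ln(alpha)-hat   : {np.log(fit.alpha_):.2f}   (truth -11.50)")
print(f"beta-hat        : {fit.beta_:.3f}  (truth 0.115)")
print(f"KM mean lifespan: {mean:.1f} +/- {se:.1f} d")
print(f"hazard at d45   : {fit.hazard(45.0):.4f} / day")
```

prints

```
deaths recorded : 125
ln(alpha)-hat   : -12.42   (truth -11.50)
beta-hat        : 0.127  (truth 0.115)
KM mean lifespan: 77.4 +/- 1.0 d
hazard at d45   : 0.0014 / day
```

One cohort of 125 flies pins down `beta` to ~10% and `ln alpha` to a few
tenths; the restricted-mean SE of ~1 day matches what such cohort sizes
typically deliver. The full pipeline (and all downstream tables) runs from
the command line:

```
metaclock run-all --seed 5 --outdir results/
```

which writes `deaths.csv`, `demography.csv`, `phenotype_correlations.csv`,
`anova_table1.csv`, `assoc_table2.csv`, `pca_scores.csv`, `clock_eval.csv`,
`age_acceleration.csv`, `aa_assoc.csv`, `truth.json`, and a `manifest.json`
recording the config hash and seed. Stage subcommands (`simulate`,
`demography`, `phenotypes`, `associate`, `clock`, `validate`) run prefixes of
the pipeline; all accept `--config config.yaml`, `--seed`, and `--outdir`.

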