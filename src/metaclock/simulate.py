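"""Synthetic cohort, phenotype, and metabolome generator.

Emulates the study design the analysis assumes: ~20 inbred genotypes of
~125 females (25 per vial, 5 vials) observed every 2 days until all die;
metabolome sampling at days 4/10/24/45/69/80 with a mixed replicate design
(5 genotypes x 4 replicates, 5 x 2, 10 x 1); and planted effect structure -
age-monotone metabolites, genotype offsets, age x genotype interactions, and
an optional coupling between late-age metabolome state and genotype lifespan
that makes short-lived genotypes look biologically older.  Every planted
effect is returned as a truth label so downstream recovery is testable.

Death times are exact draws from the Gompertz-Makeham law: the Gompertz
component by closed-form inverse CDF, the Makeham component as a competing
exponential; their minimum has exactly the GM hazard.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demography import gm_mean_lifespan, gm_survival
from .tables import DeathTable, MetaboliteMatrix

DEFAULT_AGES = (4, 10, 24, 45, 69, 80)
# ln(alpha) in [-16.5, -6.5] and beta in [0.11, 0.19] with strong negative
# coupling give 20-genotype populations whose mean lifespans typically span
# short (<50 d) through long (>65 d) cohorts while covering the parameter
# extremes seen in real inbred fly panels.
DEFAULT_ALPHA_RANGE = (float(np.exp(-16.5)), float(np.exp(-6.5)))
DEFAULT_BETA_RANGE = (0.11, 0.19)


@dataclass
class GenotypeSpec:
    """Demographic ground truth for one simulated genotype.

    alpha/beta/makeham are the GM hazard parameters (day^-1); the cohort has
    ``n_vials`` vials of 25 females each unless ``n_flies`` overrides it.
    """

    genotype_id: str
    alpha: float
    beta: float
    makeham: float = 0.0
    n_vials: int = 5
    n_flies: int | None = None

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or self.makeham < 0:
            raise ValueError("alpha, beta, makeham must be non-negative")
        if self.alpha == 0 and self.makeham == 0:
            raise ValueError("alpha and makeham cannot both be 0 (no mortality)")
        if self.n_flies is None:
            self.n_flies = 25 * self.n_vials

    def mean_lifespan(self) -> float:
        return gm_mean_lifespan(self.alpha, self.beta, self.makeham)


def sample_gm_death_times(
    alpha: float, beta: float, makeham: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Exact GM death times: inverse-CDF Gompertz vs competing exponential.

    For the Gompertz component, S(t) = exp(-(alpha/beta)(e^{beta t}-1)) gives
    T = (1/beta) * ln(1 - (beta/alpha) * ln U) for U ~ Uniform(0,1).
    """
    if alpha == 0 and beta == 0 and makeham == 0:
        raise ValueError("degenerate spec: all hazard parameters are 0")
    t_gomp = np.full(n, np.inf)
    if alpha > 0:
        u = rng.uniform(size=n)
        if beta > 0:
            t_gomp = np.log1p(-(beta / alpha) * np.log(u)) / beta
        else:
            t_gomp = -np.log(u) / alpha
    t_mak = rng.exponential(1.0 / makeham, size=n) if makeham > 0 else np.full(n, np.inf)
    return np.minimum(t_gomp, t_mak)


def simulate_gm_deaths(
    spec: GenotypeSpec, observe_interval: float = 2.0, seed=None
) -> DeathTable:
    """Simulate one cohort and bin deaths into scheduled observation windows.

    Each fly's death time falls into window ``[k*interval, (k+1)*interval)``;
    the table records the count per (vial, window).  Total deaths always
    equal ``spec.n_flies``.
    """
    if observe_interval <= 0:
        raise ValueError("observe_interval must be positive")
    rng = np.random.default_rng(seed)
    times = sample_gm_death_times(spec.alpha, spec.beta, spec.makeham, spec.n_flies, rng)
    vials = np.arange(spec.n_flies) % spec.n_vials
    k = np.floor(times / observe_interval).astype(int)
    df = (
        pd.DataFrame({"vial": vials, "k": k})
        .groupby(["vial", "k"])
        .size()
        .rename("n_dead")
        .reset_index()
    )
    df["vial"] = df["vial"].map(lambda v: f"v{v + 1}")
    df["interval_start"] = df["k"] * observe_interval
    df["interval_end"] = (df["k"] + 1) * observe_interval
    return DeathTable(
        spec.genotype_id,
        df[["vial", "interval_start", "interval_end", "n_dead"]],
    )


def simulate_population(
    n_genotypes: int = 20,
    alpha_range: tuple[float, float] = DEFAULT_ALPHA_RANGE,
    beta_range: tuple[float, float] = DEFAULT_BETA_RANGE,
    sm_coupling: float = -0.8,
    makeham: float = 5e-4,
    n_vials: int = 5,
    observe_interval: float = 2.0,
    seed=None,
) -> tuple[list[GenotypeSpec], dict[str, DeathTable]]:
    """Draw a genotype panel with Strehler-Mildvan-coupled (ln alpha, beta).

    (ln alpha, beta) pairs come from a bivariate normal whose means/SDs are
    set from the ranges (mean = midpoint, SD = quarter-range) and whose
    correlation is ``sm_coupling`` (<= 0), so the negative ln(alpha)-beta
    correlation is recoverable downstream.
    """
    if n_genotypes < 3:
        raise ValueError("need at least 3 genotypes (correlations undefined below that)")
    if not (-1.0 <= sm_coupling <= 0.0):
        raise ValueError("sm_coupling must lie in [-1, 0]")
    if alpha_range[0] <= 0 or beta_range[0] < 0:
        raise ValueError("parameter ranges must be positive")
    rng = np.random.default_rng(seed)
    la_lo, la_hi = np.log(alpha_range[0]), np.log(alpha_range[1])
    mu = [0.5 * (la_lo + la_hi), 0.5 * (beta_range[0] + beta_range[1])]
    sd = [0.25 * (la_hi - la_lo), 0.25 * (beta_range[1] - beta_range[0])]
    cov = [
        [sd[0] ** 2, sm_coupling * sd[0] * sd[1]],
        [sm_coupling * sd[0] * sd[1], sd[1] ** 2],
    ]
    draws = rng.multivariate_normal(mu, cov, size=n_genotypes)
    specs, tables = [], {}
    for i, (ln_a, b) in enumerate(draws):
        spec = GenotypeSpec(
            genotype_id=f"g{i + 1:02d}",
            alpha=float(np.exp(ln_a)),
            beta=float(max(b, 1e-3)),
            makeham=makeham,
            n_vials=n_vials,
        )
        specs.append(spec)
        tables[spec.genotype_id] = simulate_gm_deaths(
            spec, observe_interval=observe_interval, seed=rng.integers(2**31)
        )
    return specs, tables


def default_replicate_design(genotype_ids: list[str]) -> dict[str, int]:
    """Mixed replicate design: 1/4 of genotypes x4 reps, 1/4 x2, rest x1."""
    n = len(genotype_ids)
    design = {}
    for i, gid in enumerate(genotype_ids):
        if i < max(n // 4, 1):
            design[gid] = 4
        elif i < max(n // 2, 2):
            design[gid] = 2
        else:
            design[gid] = 1
    return design


@dataclass
class MetabolomeSimConfig:
    """Planted-effect configuration for the metabolome generator.

    Effect-class proportions default to the observed fractions of metabolites
    with age increase / age decrease / genotype / interaction effects
    (33.3% / 35.6% / 93.1% / 42.5%); effect sizes are generator parameters
    (the study reports proportions, not sizes) calibrated by pilot simulation
    to high power at FDR 0.01 under the default replicate design.

    ``aa_coupling`` is in days of biological-age shift per day of lifespan
    deficit relative to the reference (median) lifespan, applied along the
    planted clock direction at the two oldest ages <= 45 d only.
    """

    n_metabolites: int = 87
    ages: tuple = DEFAULT_AGES
    frac_age_increase: float = 0.333
    frac_age_decrease: float = 0.356
    frac_genotype: float = 0.931
    frac_interaction: float = 0.425
    clock_signal_n: int = 60
    aa_coupling: float = 0.5
    noise_sd: float = 0.5
    age_amplitude: float = 1.2
    genotype_sd: float = 0.8
    interaction_sd: float = 1.0
    baseline_mean: float = 10.0
    baseline_sd: float = 1.5
    dropout_survival: float = 0.05
    replicate_design: dict | None = None
    reference_lifespan: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "frac_age_increase": self.frac_age_increase,
            "frac_age_decrease": self.frac_age_decrease,
            "frac_genotype": self.frac_genotype,
            "frac_interaction": self.frac_interaction,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.frac_age_increase + self.frac_age_decrease > 1.0:
            raise ValueError("frac_age_increase + frac_age_decrease must be <= 1")
        if self.clock_signal_n > self.n_metabolites:
            raise ValueError("clock_signal_n cannot exceed n_metabolites")


def simulate_metabolome(
    genotypes: list[GenotypeSpec],
    config: MetabolomeSimConfig,
    lifespans: dict[str, float] | None = None,
) -> tuple[MetaboliteMatrix, dict]:
    """Generate a raw (positive-intensity) metabolite matrix plus truth labels.

    Signals are planted on the latent log scale and exponentiated around
    metabolite-specific baselines, so the standard preprocessing (log, then
    per-sample center/scale) recovers them.  Genotypes drop out of late
    sampling ages once their GM survival falls below ``dropout_survival``
    (ages <= 45 d are always sampled), mirroring the unbalanced late-age
    design of longitudinal cohort studies.
    """
    rng = np.random.default_rng(config.seed)
    gids = [g.genotype_id for g in genotypes]
    if lifespans is None:
        lifespans = {g.genotype_id: g.mean_lifespan() for g in genotypes}
    design = config.replicate_design or default_replicate_design(gids)
    unknown = set(design) - set(gids)
    if unknown:
        raise ValueError(f"replicate_design references unknown genotypes: {sorted(unknown)}")
    missing = set(gids) - set(design)
    if missing:
        raise ValueError(f"replicate_design missing genotypes: {sorted(missing)}")

    m = config.n_metabolites
    names = [f"met{i + 1:03d}" for i in range(m)]
    n_inc = int(round(config.frac_age_increase * m))
    n_dec = int(round(config.frac_age_decrease * m))
    order = rng.permutation(m)
    age_dir = np.zeros(m)
    age_dir[order[:n_inc]] = 1.0
    age_dir[order[n_inc : n_inc + n_dec]] = -1.0
    geno_flag = rng.uniform(size=m) < config.frac_genotype
    inter_flag = rng.uniform(size=m) < config.frac_interaction
    age_affected = np.flatnonzero(age_dir != 0)
    clock_idx = age_affected[
        rng.permutation(len(age_affected))[: min(config.clock_signal_n, len(age_affected))]
    ]
    in_clock = np.zeros(m, dtype=bool)
    in_clock[clock_idx] = True

    ages = np.asarray(config.ages, dtype=float)
    age_center = ages.mean()
    age_scale = 0.5 * (ages.max() - ages.min())
    amp = config.age_amplitude * rng.uniform(0.6, 1.4, size=m)
    slope_per_day = age_dir * amp / age_scale  # latent units per day
    geno_eff = rng.normal(0.0, config.genotype_sd, size=(len(gids), m)) * geno_flag
    inter_eff = rng.normal(0.0, config.interaction_sd, size=(len(gids), m)) * inter_flag
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=m)

    ref_ls = (
        config.reference_lifespan
        if config.reference_lifespan is not None
        else float(np.median([lifespans[g] for g in gids]))
    )
    pre45 = sorted(a for a in ages if a <= 45)
    shift_ages = set(pre45[-2:])  # the two oldest ages <= 45 d

    meta_rows, value_rows = [], []
    blocks = {g: (1 if i < (len(gids) + 1) // 2 else 2) for i, g in enumerate(gids)}
    for gi, gid in enumerate(gids):
        spec = genotypes[gi]
        for age in ages:
            if age > 45 and gm_survival(age, spec.alpha, spec.beta, spec.makeham) < (
                config.dropout_survival
            ):
                continue
            for rep in range(1, design[gid] + 1):
                z = (age - age_center) / age_scale
                val = (
                    age_dir * amp * z
                    + geno_eff[gi]
                    + inter_eff[gi] * z
                    + rng.normal(0.0, config.noise_sd, size=m)
                )
                if config.aa_coupling != 0.0 and age in shift_ages:
                    shift_days = config.aa_coupling * (ref_ls - lifespans[gid])
                    val = val + slope_per_day * in_clock * shift_days
                meta_rows.append(
                    {
                        "sample_id": f"{gid}_d{int(age):02d}_r{rep}",
                        "genotype_id": gid,
                        "age_day": float(age),
                        "replicate": rep,
                        "block": blocks[gid],
                        "batch": rep,
                    }
                )
                value_rows.append(np.exp(baseline + val))

    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    values = pd.DataFrame(np.asarray(value_rows), index=meta.index, columns=names)
    truth = {
        "age_class": {
            name: ("increase" if d > 0 else "decrease" if d < 0 else "none")
            for name, d in zip(names, age_dir)
        },
        "genotype_effect": {n: bool(f) for n, f in zip(names, geno_flag)},
        "interaction_effect": {n: bool(f) for n, f in zip(names, inter_flag)},
        "in_clock": {n: bool(f) for n, f in zip(names, in_clock)},
        "slope_per_day": {n: float(s) for n, s in zip(names, slope_per_day)},
        "reference_lifespan": ref_ls,
        "aa_coupling": config.aa_coupling,
        "shift_ages": sorted(shift_ages),
        "lifespans": {g: float(lifespans[g]) for g in gids},
    }
    return MetaboliteMatrix(meta, values), truth


def simulate_phenotypes(
    genotypes: list[GenotypeSpec],
    lifespans: dict[str, float] | None = None,
    activity_coupling: float = 0.1,
    activity_noise_sd: float = 0.25,
    activity_slope_mean: float = -1.5,
    activity_slope_sd: float = 0.2,
    fecundity_noise_sd: float = 0.15,
    seed=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate weekly climbing-activity and early-age fecundity tables.

    Activity declines linearly over weeks 3-6 with the week-5 level coupled
    to genotype lifespan by ``activity_coupling`` (activity units per day of
    lifespan); fecundity (offspring per female-day at days 8 and 12) varies
    among genotypes but is drawn independent of lifespan.
    """
    rng = np.random.default_rng(seed)
    if lifespans is None:
        lifespans = {g.genotype_id: g.mean_lifespan() for g in genotypes}
    ref = float(np.median(list(lifespans.values())))
    act_rows, fec_rows = [], []
    for g in genotypes:
        ls = lifespans[g.genotype_id]
        level5 = 6.0 + activity_coupling * (ls - ref) + rng.normal(0.0, activity_noise_sd)
        slope = activity_slope_mean + (
            rng.normal(0.0, activity_slope_sd) if activity_slope_sd > 0 else 0.0
        )
        for week in range(1, 7):
            if week >= 3:
                a = level5 + slope * (week - 5)
            else:
                a = level5 + slope * (3 - 5) + rng.normal(0.0, 0.8)
            a += rng.normal(0.0, activity_noise_sd) if activity_noise_sd > 0 else 0.0
            act_rows.append(
                {"genotype": g.genotype_id, "week": week, "mean_activity": max(a, 0.0)}
            )
        fec_mean = float(np.exp(rng.normal(np.log(2.0), 0.4)))
        for day in (8, 12):
            rate = fec_mean * float(np.exp(rng.normal(0.0, fecundity_noise_sd)))
            fec_rows.append(
                {"genotype": g.genotype_id, "age_day": day, "offspring_per_female_day": rate}
            )
    return pd.DataFrame(act_rows), pd.DataFrame(fec_rows)


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
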