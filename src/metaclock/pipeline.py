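"""End-to-end pipeline: simulate -> demography -> phenotypes -> metabolome -> clock.

Every stage reads and writes plain CSV tables so intermediate results can be
inspected or swapped for real data; a run manifest records the configuration
hash, seed, and package versions for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clock as clock_mod
from . import metabolome, phenotypes, simulate
from .demography import lifespan_variance_model, log_rank, strehler_mildvan, summarize_demography
from .tables import MetaboliteMatrix, read_death_tables, write_death_tables

logger = logging.getLogger(__name__)

EXIT_VALIDATION = 2
EXIT_NUMERICAL = 3


@dataclass
class ClockConfig:
    """Practical tuning grid for pipeline runs (override via YAML for the
    exhaustive grid exposed by :func:`metaclock.clock.default_lambda2_grid`)."""

    lambda1_grid: tuple = (0.0, 0.5, 1.0)
    lambda2_n_small: int = 10
    lambda2_n_large: int = 20
    n_repeats: int = 20
    test_fraction: float = 0.2
    cv_folds: int = 5

    def lambda2_grid(self) -> np.ndarray:
        return np.unique(
            np.concatenate(
                [
                    np.linspace(1e-6, 1, self.lambda2_n_small),
                    np.linspace(1, 1000, self.lambda2_n_large),
                ]
            )
        )


@dataclass
class PipelineConfig:
    outdir: str = "results"
    seed: int = 0
    simulate: bool = True
    n_genotypes: int = 20
    qc_threshold: float = 1 / 3
    fdr_table1: float = 0.01
    fdr_table2: float = 0.2
    cutpoints: tuple = (50.0, 65.0)
    assoc_ages: tuple = (4.0, 10.0, 24.0, 45.0)
    aa_age: float = 45.0
    aa_coupling: float = 0.5
    clock: ClockConfig = field(default_factory=ClockConfig)
    # used when simulate is False:
    deaths_csv: str | None = None
    metabolome_csv: str | None = None
    activity_csv: str | None = None
    fecundity_csv: str | None = None

    def __post_init__(self) -> None:
        for name in ("qc_threshold", "fdr_table1", "fdr_table2"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if not self.cutpoints[0] < self.cutpoints[1]:
            raise ValueError("lifespan-group cutpoints must be increasing")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        clock_cfg = ClockConfig(**{k: tuple(v) if isinstance(v, list) else v
                                   for k, v in raw.pop("clock", {}).items()})
        raw = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
        return cls(clock=clock_cfg, **raw)


def _config_hash(config: PipelineConfig) -> str:
    canon = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def validate_tables(paths: dict[str, str]) -> list[dict]:
    """Schema/consistency checks across the input tables.

    Returns a list of {level, message} records; 'error' entries should abort
    the run.
    """
    report = []

    def err(msg):
        report.append({"level": "error", "message": msg})

    def warn(msg):
        report.append({"level": "warning", "message": msg})

    genotypes = {}
    for key, cols in (
        ("deaths", {"genotype", "vial", "interval_start", "interval_end", "n_dead"}),
        ("activity", {"genotype", "week", "mean_activity"}),
        ("fecundity", {"genotype", "age_day", "offspring_per_female_day"}),
    ):
        path = paths.get(key)
        if path is None:
            continue
        if not Path(path).exists():
            err(f"{key}: file not found: {path}")
            continue
        df = pd.read_csv(path)
        missing = cols - set(df.columns)
        if missing:
            err(f"{key}: missing columns {sorted(missing)}")
            continue
        genotypes[key] = set(df["genotype"].astype(str))

    path = paths.get("metabolome")
    if path is not None:
        if not Path(path).exists():
            err(f"metabolome: file not found: {path}")
        else:
            try:
                mat = MetaboliteMatrix.from_csv(path)
            except ValueError as e:
                err(f"metabolome: {e}")
            else:
                genotypes["metabolome"] = set(mat.samples["genotype_id"].astype(str))
                vals = mat.values.to_numpy()
                bad = np.argwhere(vals <= 0)
                if len(bad):
                    i, j = bad[0]
                    err(
                        "metabolome: non-positive intensity at sample "
                        f"{mat.values.index[i]!r}, metabolite {mat.values.columns[j]!r}"
                    )

    if "deaths" in genotypes:
        for key in set(genotypes) - {"deaths"}:
            extra = genotypes[key] - genotypes["deaths"]
            if extra:
                warn(f"{key}: genotypes absent from deaths table: {sorted(extra)}")
    return report


STAGES = ("simulate", "demography", "phenotypes", "associate", "clock")


def run_pipeline(config: PipelineConfig, until: str = "clock") -> dict:
    """Execute the stages in order up to ``until``, writing every output table.

    Returns a report dict with the headline statistics each stage computed.
    """
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}; choose from {STAGES}")
    stop = STAGES.index(until)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    rng = np.random.SeedSequence(config.seed)
    seeds = rng.generate_state(8) % (2**31)
    report: dict = {"seed": config.seed}

    # -- stage 1: inputs ------------------------------------------------------
    if config.simulate:
        logger.info("simulating %d genotypes", config.n_genotypes)
        specs, tables = simulate.simulate_population(
            n_genotypes=config.n_genotypes, seed=int(seeds[0])
        )
        lifespans = {s.genotype_id: s.mean_lifespan() for s in specs}
        cfg = simulate.MetabolomeSimConfig(aa_coupling=config.aa_coupling, seed=int(seeds[1]))
        raw_mat, truth = simulate.simulate_metabolome(specs, cfg, lifespans=lifespans)
        activity, fecundity = simulate.simulate_phenotypes(
            specs, lifespans=lifespans, seed=int(seeds[2])
        )
        write_death_tables(tables, outdir / "deaths.csv")
        raw_mat.to_csv(outdir / "metabolome.csv")
        activity.to_csv(outdir / "activity.csv", index=False)
        fecundity.to_csv(outdir / "fecundity.csv", index=False)
        simulate.write_truth(truth, outdir / "truth.json")
    else:
        paths = {
            "deaths": config.deaths_csv,
            "metabolome": config.metabolome_csv,
            "activity": config.activity_csv,
            "fecundity": config.fecundity_csv,
        }
        problems = validate_tables(paths)
        errors = [r for r in problems if r["level"] == "error"]
        if errors:
            raise FileNotFoundError("; ".join(r["message"] for r in errors))
        tables = read_death_tables(config.deaths_csv)
        raw_mat = MetaboliteMatrix.from_csv(config.metabolome_csv)
        activity = pd.read_csv(config.activity_csv)
        fecundity = pd.read_csv(config.fecundity_csv)
    if stop == 0:
        return _finish(config, outdir, report, t0)

    # -- stage 2: demography ---------------------------------------------------
    logger.info("fitting demography for %d genotypes", len(tables))
    demo = summarize_demography(tables)
    demo.to_csv(outdir / "demography.csv", index=False, float_format="%.10g")
    chi2, df, p = log_rank(list(tables.values()))
    report["log_rank"] = {"chi2": chi2, "df": df, "p": p}
    report["lifespan_model"] = lifespan_variance_model(demo)
    rho, p_sm = strehler_mildvan(demo)
    report["strehler_mildvan"] = {"rho": rho, "p": p_sm}
    if stop == 1:
        return _finish(config, outdir, report, t0)

    # -- stage 3: phenotypes ---------------------------------------------------
    pheno = phenotypes.phenotype_demography_correlations(activity, fecundity, demo)
    pheno.to_csv(outdir / "phenotype_correlations.csv", index=False, float_format="%.10g")
    if stop == 2:
        return _finish(config, outdir, report, t0)

    # -- stage 4: metabolome statistics ---------------------------------------
    logger.info("preprocessing metabolome (%d samples)", raw_mat.n_samples)
    mat = metabolome.preprocess(raw_mat, qc_threshold=config.qc_threshold)
    anova = metabolome.fit_age_genotype_model(mat, fdr=config.fdr_table1)
    anova.to_csv(outdir / "anova_table1.csv", index=False, float_format="%.10g")
    scores, loadings, varexp = metabolome.pca_overview(mat)
    scores.to_csv(outdir / "pca_scores.csv", float_format="%.10g")
    pc1_tbl = metabolome.pc1_lifespan_group_model(scores, demo, config.cutpoints)
    report["pc1_group_model"] = {
        term: {"F": float(row["F"]), "p": float(row["PR(>F)"])}
        for term, row in pc1_tbl.iterrows()
        if np.isfinite(row["F"])
    }
    assoc_frames = [
        metabolome.level_demography_assoc(mat, demo, age=a, fdr=config.fdr_table2)
        for a in config.assoc_ages
        if (mat.samples["age_day"] == a).any()
    ]
    slopes = metabolome.trajectory_slopes(mat)
    assoc_frames.append(
        metabolome.trajectory_demography_assoc(slopes, demo, fdr=config.fdr_table2)
    )
    assoc = pd.concat(assoc_frames, ignore_index=True)
    assoc.to_csv(outdir / "assoc_table2.csv", index=False, float_format="%.10g")
    if stop == 3:
        return _finish(config, outdir, report, t0)

    # -- stage 5: clock --------------------------------------------------------
    logger.info("tuning the metabolome clock")
    hp = clock_mod.ClockHyperparams(
        lambda1_grid=tuple(config.clock.lambda1_grid),
        lambda2_grid=config.clock.lambda2_grid(),
        n_repeats=config.clock.n_repeats,
        test_fraction=config.clock.test_fraction,
        cv_folds=config.clock.cv_folds,
        seed=int(seeds[3]),
    )
    evaluation = clock_mod.tune_and_evaluate(mat, hp)
    evaluation.per_repeat.to_csv(outdir / "clock_eval.csv", index=False, float_format="%.10g")
    aa = clock_mod.loocv_predict(
        mat, evaluation.consensus_lambda1, evaluation.consensus_lambda2
    )
    aa.to_csv(outdir / "age_acceleration.csv", index=False, float_format="%.10g")
    aa_assoc = clock_mod.aa_demography_assoc(aa, demo, at_age=config.aa_age)
    aa_assoc.to_csv(outdir / "aa_assoc.csv", index=False, float_format="%.10g")

    from sklearn.metrics import r2_score

    report["clock"] = {
        "median_test_r2": float(evaluation.per_repeat["test_r2"].median()),
        "consensus_lambda1": evaluation.consensus_lambda1,
        "consensus_lambda2": evaluation.consensus_lambda2,
        "loocv_r2": float(r2_score(aa["age_day"], aa["predicted_age"])),
    }
    report["aa_assoc"] = {
        row["parameter"]: {"rho": row["rho"], "p": row["p_rho"]}
        for _, row in aa_assoc.iterrows()
    }

    return _finish(config, outdir, report, t0)


def _finish(config: PipelineConfig, outdir: Path, report: dict, t0: float) -> dict:
    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "config": asdict(config),
        "versions": _versions(),
        "tables": sorted(p.name for p in outdir.glob("*.csv")),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    logger.info("pipeline finished in %.1f s", time.time() - t0)
    return report


def _versions() -> dict:
    import sklearn
    import scipy
    import statsmodels

    from . import __version__

    return {
        "metaclock": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "sklearn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
    }
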