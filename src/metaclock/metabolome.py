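"""Metabolome preprocessing, per-metabolite linear models, and PCA overview.

Preprocessing follows the standard targeted-LC-MS convention: natural-log
transform for normality, then each sample (row) centered and scaled to mean 0
and SD 1 across metabolites, after a robust QC screen that drops samples in
which an excessive fraction of metabolites is abnormal.

The per-metabolite two-way model

    level = mu + Age + Genotype + Age x Genotype + eps     (age categorical)

is fitted to all metabolites simultaneously through shared-design QR
projections (the design is identical across metabolites), with type-II
F-tests and Benjamini-Hochberg FDR within each term family.  Associations of
age-specific levels and of age trajectories with demographic parameters
(mean lifespan, ln alpha, beta) are simple per-metabolite regressions at the
genotype level, since demography is a genotype-level quantity.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .tables import MetaboliteMatrix

logger = logging.getLogger(__name__)

FIRST_FOUR_AGES = (4.0, 10.0, 24.0, 45.0)
DEMOGRAPHIC_PARAMS = ("mean_lifespan", "ln_alpha", "beta")


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def _row_standardize(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    return (values - mu) / sd


def preprocess(
    raw: MetaboliteMatrix, qc_threshold: float = 1 / 3, log_transform: bool = True
) -> MetaboliteMatrix:
    """Log-transform, QC-screen, and row-standardize a raw intensity matrix.

    A sample is dropped when the fraction of its metabolites with
    |robust z| > 4 (median/MAD across samples, per metabolite, on the log
    scale) exceeds ``qc_threshold``; each drop is logged with its reason.
    Already-normalized input passes through standardization idempotently when
    ``log_transform=False``.
    """
    vals = raw.values.to_numpy(dtype=float)
    if log_transform:
        bad = np.argwhere(vals <= 0)
        if len(bad):
            i, j = bad[0]
            raise ValueError(
                f"non-positive intensity at sample {raw.values.index[i]!r}, "
                f"metabolite {raw.values.columns[j]!r}"
            )
        vals = np.log(vals)

    med = np.median(vals, axis=0, keepdims=True)
    mad = scipy.stats.median_abs_deviation(vals, axis=0, scale="normal")
    mad = np.where(mad <= 0, np.inf, mad)
    frac_abnormal = (np.abs(vals - med) / mad > 4).mean(axis=1)
    keep = frac_abnormal <= qc_threshold
    dropped = []
    for sid, frac in zip(raw.values.index[~keep], frac_abnormal[~keep]):
        reason = f"{sid}: {frac:.0%} of metabolites abnormal (|robust z| > 4)"
        logger.warning("QC drop %s", reason)
        dropped.append(reason)

    vals = _row_standardize(vals[keep])
    return MetaboliteMatrix(
        raw.samples.loc[keep].copy(),
        pd.DataFrame(vals, index=raw.values.index[keep], columns=raw.values.columns),
        normalized=True,
        qc_dropped=list(raw.qc_dropped) + dropped,
    )


def balanced_ages(mat: MetaboliteMatrix, min_fraction: float = 0.8) -> list[float]:
    """Sampling ages at which at least ``min_fraction`` of genotypes are present."""
    n_geno = mat.samples["genotype_id"].nunique()
    counts = mat.samples.groupby("age_day")["genotype_id"].nunique()
    return sorted(counts[counts >= min_fraction * n_geno].index)


def _rss_matrix(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, int]:
    """Residual sum of squares of Y's columns on design X, plus X's rank."""
    q, r = np.linalg.qr(X)
    rank = int(np.sum(np.abs(np.diag(r)) > np.abs(r).max() * 1e-10 * max(X.shape)))
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design")
    resid = Y - q @ (q.T @ Y)
    return np.sum(resid**2, axis=0), rank


def _design(meta: pd.DataFrame, age: bool, geno: bool, inter: bool) -> np.ndarray:
    cols = [np.ones(len(meta))]
    a = pd.get_dummies(meta["age_day"].astype("category"), drop_first=True, dtype=float)
    g = pd.get_dummies(meta["genotype_id"].astype("category"), drop_first=True, dtype=float)
    if age:
        cols.append(a.to_numpy())
    if geno:
        cols.append(g.to_numpy())
    if inter:
        an, gn = a.to_numpy(), g.to_numpy()
        cols.append((an[:, :, None] * gn[:, None, :]).reshape(len(meta), -1))
    return np.column_stack(cols)


def fit_age_genotype_model(
    mat: MetaboliteMatrix, fdr: float = 0.01, ages: list | None = None
) -> pd.DataFrame:
    """Two-way fixed-effects model per metabolite with BH-FDR per term family.

    Age enters as a categorical factor; the direction label ('increase' /
    'decrease') for age-significant metabolites comes from the sign of the
    OLS slope of level on numeric age.  By default only ages at which most
    genotypes are still represented are analyzed, avoiding the unbalanced
    late-age design.
    """
    if ages is None:
        ages = balanced_ages(mat)
    sub = mat.subset(mat.samples["age_day"].isin(ages))
    meta = sub.samples
    if meta["genotype_id"].nunique() < 2 or meta["age_day"].nunique() < 2:
        raise ValueError("need at least 2 genotypes and 2 ages")
    Y = sub.values.to_numpy(dtype=float)
    n = len(meta)

    X_full = _design(meta, True, True, True)
    X_add = _design(meta, True, True, False)
    X_age = _design(meta, True, False, False)
    X_gen = _design(meta, False, True, False)
    if n - X_full.shape[1] <= 0:
        raise ValueError("no residual degrees of freedom for the interaction model")

    interaction_ok = True
    try:
        rss_full, rank_full = _rss_matrix(X_full, Y)
    except np.linalg.LinAlgError:
        interaction_ok = False
        warnings.warn("empty age x genotype cells; interaction term inestimable")
        rss_full, rank_full = _rss_matrix(X_add, Y)
    rss_add, rank_add = _rss_matrix(X_add, Y)
    rss_age, rank_age = _rss_matrix(X_age, Y)
    rss_gen, rank_gen = _rss_matrix(X_gen, Y)

    df_res = n - rank_full
    mse = rss_full / df_res

    # type-II tests: each term against the additive model, F on full-model MSE
    if interaction_ok:
        df_int = rank_full - rank_add
        f_int = ((rss_add - rss_full) / df_int) / mse
        p_int = scipy.stats.f.sf(f_int, df_int, df_res)
    else:
        p_int = np.full(Y.shape[1], np.nan)
    df_age_term = rank_add - rank_gen
    f_age = ((rss_gen - rss_add) / df_age_term) / mse
    p_age = scipy.stats.f.sf(f_age, df_age_term, df_res)
    df_gen_term = rank_add - rank_age
    f_gen = ((rss_age - rss_add) / df_gen_term) / mse
    p_gen = scipy.stats.f.sf(f_gen, df_gen_term, df_res)

    # numeric-age slope for the direction label
    x = meta["age_day"].to_numpy(float)
    xc = x - x.mean()
    slope = xc @ Y / np.sum(xc**2)

    out = pd.DataFrame(
        {
            "metabolite": sub.values.columns,
            "p_age": p_age,
            "p_genotype": p_gen,
            "p_interaction": p_int,
            "age_slope": slope,
        }
    )
    out["q_age"] = bh_fdr(out["p_age"])
    out["q_genotype"] = bh_fdr(out["p_genotype"])
    out["q_interaction"] = bh_fdr(out["p_interaction"])
    out["age_direction"] = np.where(
        out["q_age"] < fdr, np.where(out["age_slope"] > 0, "increase", "decrease"), "none"
    )
    return out


def pca_overview(mat: MetaboliteMatrix):
    """Centered PCA of the normalized matrix.

    PC1 is sign-oriented so its correlation with sample age is non-negative.
    Returns (scores, loadings, variance_explained); scores carry the sample
    metadata columns alongside the PCs.
    """
    if mat.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    X = mat.values.to_numpy(dtype=float)
    k = min(X.shape)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(X)
    loadings = pca.components_.T.copy()
    age = mat.samples["age_day"].to_numpy(float)
    if np.corrcoef(scores[:, 0], age)[0, 1] < 0:
        scores[:, 0] *= -1
        loadings[:, 0] *= -1
    pc_cols = [f"PC{i + 1}" for i in range(k)]
    scores_df = mat.samples.join(
        pd.DataFrame(scores, index=mat.values.index, columns=pc_cols)
    )
    loadings_df = pd.DataFrame(loadings, index=mat.values.columns, columns=pc_cols)
    return scores_df, loadings_df, pca.explained_variance_.copy()


def lifespan_groups(summaries: pd.DataFrame, cutpoints=(50.0, 65.0)) -> pd.Series:
    """Short/medium/long lifespan group per genotype from mean lifespan."""
    lo, hi = cutpoints
    if not lo < hi:
        raise ValueError("cutpoints must be increasing")
    ls = summaries.set_index("genotype")["mean_lifespan"]
    return pd.Series(
        np.where(ls < lo, "short", np.where(ls > hi, "long", "medium")),
        index=ls.index,
        name="lifespan_group",
    )


def pc1_lifespan_group_model(
    scores: pd.DataFrame, summaries: pd.DataFrame, cutpoints=(50.0, 65.0)
) -> pd.DataFrame:
    """ANOVA of PC1 ~ age + lifespan group + age x group (age numeric).

    A significant interaction means metabolome aging trajectories differ
    among short/medium/long-lived genotypes.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    groups = lifespan_groups(summaries, cutpoints)
    df = scores.copy()
    df["group"] = df["genotype_id"].map(groups)
    present = df["group"].dropna().nunique()
    if present < 2:
        raise ValueError("need at least 2 lifespan groups")
    if present < 3:
        warnings.warn("only 2 lifespan groups present; degraded design")
    model = smf.ols("PC1 ~ age_day * C(group)", data=df).fit()
    return sm.stats.anova_lm(model, typ=2)


def _genotype_level_assoc(
    levels: pd.DataFrame, summaries: pd.DataFrame, predictor_name: str
) -> pd.DataFrame:
    """Per-metabolite regression of a genotype-level quantity on each phi_k."""
    demo = summaries.set_index("genotype")[list(DEMOGRAPHIC_PARAMS)]
    common = levels.index.intersection(demo.index)
    if len(common) < 5:
        raise ValueError("fewer than 5 genotypes shared with demography")
    Y = levels.loc[common].to_numpy(dtype=float)
    rows = []
    for pname in DEMOGRAPHIC_PARAMS:
        x = demo.loc[common, pname].to_numpy(float)
        xc = x - x.mean()
        sxx = np.sum(xc**2)
        const = np.ptp(Y, axis=0) == 0
        slope = xc @ Y / sxx
        resid = Y - Y.mean(axis=0) - np.outer(xc, slope)
        dof = len(common) - 2
        se = np.sqrt(np.sum(resid**2, axis=0) / dof / sxx)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = slope / se
        p = 2 * scipy.stats.t.sf(np.abs(tstat), dof)
        rho = np.array(
            [
                scipy.stats.spearmanr(x, Y[:, j]).statistic if not const[j] else np.nan
                for j in range(Y.shape[1])
            ]
        )
        p = np.where(const, np.nan, p)
        slope = np.where(const, np.nan, slope)
        if const.any():
            warnings.warn(
                f"{int(const.sum())} constant metabolites skipped for {pname} association"
            )
        sub = pd.DataFrame(
            {
                "metabolite": levels.columns,
                "predictor": predictor_name,
                "parameter": pname,
                "estimate": slope,
                "rho": rho,
                "p": p,
            }
        )
        sub["q"] = bh_fdr(sub["p"])
        rows.append(sub)
    return pd.concat(rows, ignore_index=True)


def level_demography_assoc(
    mat: MetaboliteMatrix, summaries: pd.DataFrame, age: float, fdr: float = 0.2
) -> pd.DataFrame:
    """Associate genotype-mean metabolite levels at one age with demography.

    One simple regression per (metabolite, parameter); BH-FDR within each
    (parameter, age) family.  ``significant`` flags q below ``fdr``.
    """
    sel = mat.samples["age_day"] == age
    if not sel.any():
        raise ValueError(f"age {age} not present in the matrix")
    sub = mat.subset(sel)
    levels = sub.values.groupby(sub.samples["genotype_id"]).mean()
    out = _genotype_level_assoc(levels, summaries, predictor_name=f"level@day{int(age)}")
    out["significant"] = out["q"] < fdr
    return out


def trajectory_slopes(mat: MetaboliteMatrix, ages_used=FIRST_FOUR_AGES) -> pd.DataFrame:
    """Per (genotype, metabolite) OLS slope of level on age (days).

    Only the early, fully-sampled ages enter by default; genotypes with fewer
    than 3 of those ages are skipped with a warning.
    """
    sel = mat.samples["age_day"].isin(ages_used)
    sub = mat.subset(sel)
    rows = {}
    for gid, idx in sub.samples.groupby("genotype_id").groups.items():
        meta = sub.samples.loc[idx]
        if meta["age_day"].nunique() < 3:
            warnings.warn(f"{gid}: fewer than 3 ages available; trajectory skipped")
            continue
        x = meta["age_day"].to_numpy(float)
        xc = x - x.mean()
        Y = sub.values.loc[idx].to_numpy(float)
        rows[gid] = xc @ Y / np.sum(xc**2)
    return pd.DataFrame.from_dict(rows, orient="index", columns=mat.values.columns)


def trajectory_demography_assoc(
    slopes: pd.DataFrame, summaries: pd.DataFrame, fdr: float = 0.2
) -> pd.DataFrame:
    """Associate per-genotype metabolite age-trajectories with demography."""
    out = _genotype_level_assoc(slopes, summaries, predictor_name="trajectory")
    out["significant"] = out["q"] < fdr
    return out
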