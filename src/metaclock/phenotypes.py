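"""Age-specific functional phenotypes and their demographic correlates.

Fecundity is offspring per female per day; climbing activity is a weekly
genotype-mean score whose week 3-6 linear decline summarizes functional
aging.  Correlations with demographic parameters use non-parametric
Spearman's rho (average ranks for ties), with exact permutation p-values at
small n where the t-approximation is unreliable.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf


def fecundity_per_female(
    n_offspring: float, n_females_alive: float, interval_days: float
) -> float:
    """Viable offspring per female per day for one vial-interval."""
    if n_females_alive <= 0:
        raise ValueError("n_females_alive must be positive")
    if interval_days <= 0:
        raise ValueError("interval_days must be positive")
    return n_offspring / (n_females_alive * interval_days)


def activity_decline_slope(series: pd.DataFrame, week_range=(3, 6)) -> float:
    """OLS slope of activity on week restricted to the decline window.

    ``series`` needs columns ``week`` and ``mean_activity``; at least three
    weeks must fall inside ``week_range``.
    """
    sel = series[(series["week"] >= week_range[0]) & (series["week"] <= week_range[1])]
    if sel["week"].nunique() < 3:
        raise ValueError("need at least 3 weeks inside the window to estimate a slope")
    slope = np.polyfit(sel["week"].to_numpy(float), sel["mean_activity"].to_numpy(float), 1)[0]
    return float(slope)


def spearman(x, y, exact_below: int = 10) -> tuple[float, float]:
    """Spearman's rho with tie-averaged ranks.

    The p-value uses the exact permutation null for n < ``exact_below``
    (enumerating all n! rank orders) and the t-approximation otherwise.
    Returns (nan, nan) when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    n = len(x)
    rho = float(scipy.stats.spearmanr(x, y).statistic)
    if n >= exact_below:
        return rho, float(scipy.stats.spearmanr(x, y).pvalue)
    # exact permutation null of |rho|
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    observed = abs(np.dot(rx, ry) / n)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        stat = abs(np.dot(rx[list(perm)], ry) / n)
        count += stat >= observed - 1e-12
        total += 1
    return rho, count / total


def phenotype_demography_correlations(
    activity: pd.DataFrame,
    fecundity: pd.DataFrame,
    summaries: pd.DataFrame,
    weeks=(3, 4, 5, 6),
    fecundity_ages=(8, 12),
) -> pd.DataFrame:
    """Spearman rho/p for each phenotype feature x demographic parameter.

    Features: activity level at each requested week, the week 3-6 activity
    decline slope, and fecundity at each requested age.  Parameters: mean
    lifespan, ln(alpha), beta.  Requires >= 5 genotypes in common; constant
    features are reported with missing rho.
    """
    features = {}
    act_wide = activity.pivot_table(index="genotype", columns="week", values="mean_activity")
    for w in weeks:
        if w in act_wide.columns:
            features[f"activity_week{w}"] = act_wide[w]
    slopes = {
        gid: activity_decline_slope(grp) for gid, grp in activity.groupby("genotype")
    }
    features["activity_decline_slope"] = pd.Series(slopes)
    fec_wide = fecundity.pivot_table(
        index="genotype", columns="age_day", values="offspring_per_female_day"
    )
    for a in fecundity_ages:
        if a in fec_wide.columns:
            features[f"fecundity_day{a}"] = fec_wide[a]

    params = summaries.set_index("genotype")[["mean_lifespan", "ln_alpha", "beta"]]
    rows = []
    for fname, fvals in features.items():
        common = fvals.index.intersection(params.index)
        if len(common) < 5:
            raise ValueError(f"{fname}: fewer than 5 genotypes shared with demography")
        for pname in params.columns:
            rho, p = spearman(fvals.loc[common], params.loc[common, pname])
            if np.isnan(rho):
                warnings.warn(f"{fname} is constant; correlation undefined")
            rows.append({"phenotype": fname, "parameter": pname, "rho": rho, "p": p})
    return pd.DataFrame(rows)


def activity_anova(activity: pd.DataFrame) -> pd.DataFrame:
    """Genotype + week factorial ANOVA of activity (convenience diagnostic)."""
    model = smf.ols("mean_activity ~ C(genotype) + C(week)", data=activity).fit()
    return sm.stats.anova_lm(model, typ=2)
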