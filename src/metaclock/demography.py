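"""Gompertz-Makeham demography from interval-censored cohort death tables.

The Gompertz-Makeham (GM) hazard is

    mu(x) = alpha * exp(beta * x) + M

with ``alpha`` the baseline (intrinsic, age-independent) mortality, ``beta``
the exponential rate of aging, and ``M`` the Makeham age-independent
(extrinsic) mortality.  Deaths recorded on a transfer schedule are only known
to intervals, so the fit maximizes the exact interval-censored likelihood

    l(alpha, beta, M) = sum_intervals n_dead * ln[S(start) - S(end)]
                        + sum_censored ln S(t_c)

rather than imputing midpoint death times.  Survival summaries (restricted
mean, log-rank) use the Kaplan-Meier machinery from lifelines with the
interval-end event-time convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.integrate
import scipy.optimize
import scipy.stats
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from sklearn.base import BaseEstimator

from .tables import DeathTable

_LN_BETA_FLOOR = np.log(1e-8)


def gm_hazard(x, alpha: float, beta: float, makeham: float = 0.0):
    """Instantaneous GM mortality rate ``alpha*exp(beta*x) + M`` at age x (days)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("age x must be non-negative")
    return alpha * np.exp(beta * x) + makeham


def gm_survival(x, alpha: float, beta: float, makeham: float = 0.0):
    """GM survival function, the closed-form integral of the hazard.

    S(x) = exp(-M*x - (alpha/beta) * (exp(beta*x) - 1)) for beta > 0, and the
    exponential limit exp(-(alpha + M)*x) at beta = 0.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("age x must be non-negative")
    with np.errstate(over="ignore"):
        if beta > 1e-12:
            cum = makeham * x + (alpha / beta) * np.expm1(beta * x)
        else:
            cum = (alpha + makeham) * x
        return np.exp(-cum)


def gm_mean_lifespan(alpha: float, beta: float, makeham: float = 0.0) -> float:
    """Mean lifespan under the GM law by adaptive quadrature of S(x)."""
    # locate an upper limit where survival is negligible
    upper = 1.0
    while gm_survival(upper, alpha, beta, makeham) > 1e-12 and upper < 1e7:
        upper *= 2.0
    val, _ = scipy.integrate.quad(
        lambda t: gm_survival(t, alpha, beta, makeham), 0.0, upper, limit=200
    )
    return float(val)


def _interval_neg_loglik(theta, starts, ends, n_dead, cens_t, n_cens, include_makeham):
    ln_a, ln_b = theta[0], theta[1]
    if ln_a > 10 or ln_b > 5:
        return 1e12
    alpha, beta = np.exp(ln_a), np.exp(ln_b)
    mak = np.exp(theta[2]) if include_makeham else 0.0
    s_start = gm_survival(starts, alpha, beta, mak)
    s_end = gm_survival(ends, alpha, beta, mak)
    prob = s_start - s_end
    if np.any(prob <= 0):
        return 1e12
    ll = float(np.sum(n_dead * np.log(prob)))
    if n_cens is not None and len(n_cens):
        s_c = gm_survival(cens_t, alpha, beta, mak)
        if np.any(s_c <= 0):
            return 1e12
        ll += float(np.sum(n_cens * np.log(s_c)))
    if not np.isfinite(ll):
        return 1e12
    return -ll


class GompertzMakehamModel(BaseEstimator):
    """Maximum-likelihood Gompertz-Makeham fit to an interval-censored death table.

    Optimization runs on the log scale (ln alpha, ln beta, ln M) with
    multi-start initialization: (ln alpha, beta) are seeded by least squares
    on the log empirical interval hazard against age, and M at half the
    earliest-interval empirical hazard.  With ``include_makeham=False`` the
    pure Gompertz model (M = 0) is fitted, which is the parameterization used
    for the Strehler-Mildvan and lifespan variance diagnostics.

    Fitted attributes: ``alpha_``, ``beta_``, ``makeham_``,
    ``log_likelihood_``, ``converged_``, ``n_obs_``.
    """

    def __init__(self, include_makeham: bool = True, n_starts: int = 4, tol: float = 1e-9):
        self.include_makeham = include_makeham
        self.n_starts = n_starts
        self.tol = tol

    def _initial_points(self, agg: pd.DataFrame, n_total: int) -> list[np.ndarray]:
        starts = agg["interval_start"].to_numpy(float)
        ends = agg["interval_end"].to_numpy(float)
        n_dead = agg["n_dead"].to_numpy(float)
        # empirical interval hazard: deaths / (at-risk * interval width)
        removed = n_dead + agg["n_censored"].to_numpy(float)
        at_risk = n_total - np.concatenate([[0.0], np.cumsum(removed)[:-1]])
        with np.errstate(divide="ignore", invalid="ignore"):
            haz = n_dead / (at_risk * (ends - starts))
        mid = 0.5 * (starts + ends)
        ok = np.isfinite(haz) & (haz > 0)
        if ok.sum() >= 2:
            slope, intercept = np.polyfit(mid[ok], np.log(haz[ok]), 1)
            b0 = max(slope, 1e-4)
            ln_a0 = intercept
        else:  # pragma: no cover - pathological tables
            b0, ln_a0 = 0.1, -10.0
        first_haz = haz[ok][0] if ok.any() else 1e-4
        ln_m0 = np.log(max(first_haz / 2.0, 1e-10))
        base = [ln_a0, np.log(b0)]
        if self.include_makeham:
            base = base + [ln_m0]
        pts = [np.array(base)]
        jitters = [(-1.5, 0.5), (1.0, -0.7), (0.0, -1.5)]
        for da, db in jitters[: max(self.n_starts - 1, 0)]:
            p = np.array(base, dtype=float)
            p[0] += da
            p[1] += db
            pts.append(p)
        return pts

    def fit(self, death_table: DeathTable) -> "GompertzMakehamModel":
        agg = death_table.aggregated()
        events = agg[agg["n_dead"] > 0]
        if len(events) < 2:
            raise ValueError(
                "need deaths in at least 2 distinct intervals to identify (alpha, beta)"
            )
        total = death_table.total_deaths
        if total < 10:
            warnings.warn(
                f"{death_table.genotype_id}: only {total} deaths; fit flagged unreliable",
                UserWarning,
            )
        starts = agg["interval_start"].to_numpy(float)
        ends = agg["interval_end"].to_numpy(float)
        n_dead = agg["n_dead"].to_numpy(float)
        cens = agg[agg["n_censored"] > 0]
        cens_t = cens["interval_end"].to_numpy(float)
        n_cens = cens["n_censored"].to_numpy(float)
        n_total = total + death_table.total_censored

        args = (starts, ends, n_dead, cens_t, n_cens, self.include_makeham)
        bounds = [(-40.0, 5.0), (_LN_BETA_FLOOR, 3.0)]
        if self.include_makeham:
            bounds.append((-30.0, 2.0))
        best = None
        for x0 in self._initial_points(agg, n_total):
            x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
            res = scipy.optimize.minimize(
                _interval_neg_loglik,
                x0,
                args=args,
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": self.tol, "gtol": 1e-7, "maxiter": 500},
            )
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun) or best.fun >= 1e11:
            raise RuntimeError(
                f"{death_table.genotype_id}: GM likelihood non-finite at all starting points"
            )
        self.alpha_ = float(np.exp(best.x[0]))
        self.beta_ = float(np.exp(best.x[1]))
        self.makeham_ = float(np.exp(best.x[2])) if self.include_makeham else 0.0
        self.log_likelihood_ = -float(best.fun)
        self.converged_ = bool(best.success)
        self.n_obs_ = int(n_total)
        self.genotype_id_ = death_table.genotype_id
        return self

    # -- derived quantities -------------------------------------------------
    def hazard(self, x):
        return gm_hazard(x, self.alpha_, self.beta_, self.makeham_)

    def survival(self, x):
        return gm_survival(x, self.alpha_, self.beta_, self.makeham_)

    def mean_lifespan(self) -> float:
        return gm_mean_lifespan(self.alpha_, self.beta_, self.makeham_)


def fit_gm(death_table: DeathTable, include_makeham: bool = True) -> GompertzMakehamModel:
    """Fit the GM model by interval-censored maximum likelihood (thin wrapper)."""
    return GompertzMakehamModel(include_makeham=include_makeham).fit(death_table)


def gm_interval_loglik(
    death_table: DeathTable, alpha: float, beta: float, makeham: float = 0.0
) -> float:
    """Interval-censored log-likelihood at arbitrary (alpha, beta, M).

    Useful for likelihood-ratio comparisons and for checking MLE dominance.
    """
    agg = death_table.aggregated()
    cens = agg[agg["n_censored"] > 0]
    theta = [np.log(alpha), np.log(max(beta, 1e-12)), np.log(max(makeham, 1e-300))]
    return -_interval_neg_loglik(
        np.array(theta),
        agg["interval_start"].to_numpy(float),
        agg["interval_end"].to_numpy(float),
        agg["n_dead"].to_numpy(float),
        cens["interval_end"].to_numpy(float),
        cens["n_censored"].to_numpy(float),
        True,
    )


def km_restricted_mean(death_table: DeathTable, tau: float | None = None):
    """Kaplan-Meier restricted mean lifespan and its Greenwood-based SE.

    The product-limit estimator is computed on interval-end event times; the
    restricted mean is the exact area under the KM step function up to ``tau``
    (default: last observed time).  The SE uses the standard Greenwood-based
    area formula  Var = sum_j A_j^2 d_j / (n_j (n_j - d_j))  with A_j the KM
    area beyond event time t_j (terms where the risk set is exhausted are
    conventionally dropped).
    """
    durations, observed = death_table.to_events()
    if len(durations) == 0:
        raise ValueError("death table has no events")
    if tau is None:
        tau = float(durations.max())
    event_times = durations[observed == 1]
    if len(event_times) and tau < event_times.min():
        raise ValueError(f"tau={tau} precedes the first event time {event_times.min()}")
    kmf = KaplanMeierFitter().fit(durations, observed)
    tbl = kmf.event_table.loc[kmf.event_table["observed"] > 0]
    t_j = tbl.index.to_numpy(float)
    d_j = tbl["observed"].to_numpy(float)
    n_j = tbl["at_risk"].to_numpy(float)
    s_j = kmf.survival_function_at_times(t_j).to_numpy(float)  # S just after t_j

    keep = t_j <= tau
    t_j, d_j, n_j, s_j = t_j[keep], d_j[keep], n_j[keep], s_j[keep]
    # exact area under the step function: S=1 on [0, t_1), s_j on [t_j, t_{j+1})
    knots = np.concatenate([[0.0], t_j, [tau]])
    steps = np.concatenate([[1.0], s_j])
    widths = np.clip(np.diff(knots), 0.0, None)
    mean = float(np.sum(widths * steps))
    # area beyond each event time
    tail = np.cumsum((widths * steps)[::-1])[::-1]  # tail[k] = area from knots[k] on
    A_j = tail[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = A_j**2 * d_j / (n_j * (n_j - d_j))
    var = float(np.sum(terms[np.isfinite(terms)]))
    return mean, float(np.sqrt(max(var, 0.0)))


def log_rank(groups: list[DeathTable]):
    """k-sample log-rank test on pooled interval-end event times.

    Returns (chi2, df, p) with df = k - 1.
    """
    if len(groups) < 2:
        raise ValueError("log-rank requires at least 2 groups")
    if not any(g.total_deaths > 0 for g in groups):
        raise ValueError("no events in any group")
    durations, events, labels = [], [], []
    for g in groups:
        d, o = g.to_events()
        durations.append(d)
        events.append(o)
        labels.extend([g.genotype_id] * len(d))
    res = multivariate_logrank_test(
        np.concatenate(durations), np.asarray(labels), np.concatenate(events)
    )
    df = len(groups) - 1
    return float(res.test_statistic), df, float(res.p_value)


@dataclass
class DemographicSummary:
    """Genotype-level demographic parameters feeding the association models."""

    genotype_id: str
    mean_lifespan: float
    mean_lifespan_se: float
    hazard_d45: float
    hazard_d60: float
    gm: GompertzMakehamModel


def summarize_demography(
    tables: dict[str, DeathTable],
    include_makeham: bool = True,
    hazard_ages: tuple[float, float] = (45.0, 60.0),
) -> pd.DataFrame:
    """Fit every genotype and assemble the demography table.

    Mid-age hazards are model-based (evaluated from the GM fit) because
    empirical bins at those ages are noisy; the GM model estimates them
    reliably between days 45 and 60.
    """
    rows = []
    for gid in sorted(tables):
        dt = tables[gid]
        fit = fit_gm(dt, include_makeham=include_makeham)
        mean, se = km_restricted_mean(dt)
        rows.append(
            {
                "genotype": gid,
                "mean_lifespan": mean,
                "mean_lifespan_se": se,
                "ln_alpha": np.log(fit.alpha_),
                "beta": fit.beta_,
                "makeham": fit.makeham_,
                "loglik": fit.log_likelihood_,
                "converged": fit.converged_,
                f"hazard_d{int(hazard_ages[0])}": float(fit.hazard(hazard_ages[0])),
                f"hazard_d{int(hazard_ages[1])}": float(fit.hazard(hazard_ages[1])),
            }
        )
    return pd.DataFrame(rows)


def lifespan_variance_model(summaries: pd.DataFrame):
    """OLS of mean lifespan on (ln alpha, beta) across genotypes.

    Returns a dict with the adjusted R^2 and marginal (type-III) F and p for
    each demographic parameter.  Requires >= 5 genotypes.
    """
    import statsmodels.formula.api as smf

    df = summaries
    if len(df) < 5:
        raise ValueError("need at least 5 genotypes")
    r = np.corrcoef(df["ln_alpha"], df["beta"])[0, 1]
    if abs(r) > 0.999:
        warnings.warn("ln_alpha and beta nearly collinear; marginal tests unstable")
    model = smf.ols("mean_lifespan ~ ln_alpha + beta", data=df).fit()
    out = {"adj_r2": float(model.rsquared_adj)}
    for name in ("ln_alpha", "beta"):
        t = model.tvalues[name]
        out[f"F_{name}"] = float(t**2)
        out[f"p_{name}"] = float(model.pvalues[name])
    out["df_resid"] = int(model.df_resid)
    return out


def strehler_mildvan(summaries: pd.DataFrame):
    """Spearman correlation of ln alpha vs beta across genotypes.

    A negative correlation (fast-aging genotypes have lower baseline
    mortality) is the Strehler-Mildvan pattern.
    """
    if len(summaries) < 3:
        raise ValueError("need at least 3 genotypes")
    rho, p = scipy.stats.spearmanr(summaries["ln_alpha"], summaries["beta"])
    return float(rho), float(p)
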