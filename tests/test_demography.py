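"""Gompertz-Makeham identities, MLE recovery, and survival summaries."""

import numpy as np
import pandas as pd
import pytest
import scipy.integrate
import scipy.stats

import metaclock as mc
from metaclock.demography import gm_interval_loglik
from metaclock.tables import DeathTable


# ---------------------------------------------------------------- hazard/survival
@pytest.mark.parametrize(
    "alpha,beta,mak,x,expected",
    [
        (np.exp(-11.5), 0.115, 0.0, 0.0, np.exp(-11.5)),  # baseline at x=0
        (np.exp(-15.9), 0.188, 0.0, 45.0, np.exp(-15.9 + 0.188 * 45)),
        (2e-3, 0.0, 1e-3, 57.0, 3e-3),  # beta=0: constant alpha+M
    ],
)
def test_gm_hazard_values(alpha, beta, mak, x, expected):
    assert mc.gm_hazard(x, alpha, beta, mak) == pytest.approx(expected, rel=1e-12)


def test_gm_hazard_rejects_negative_age():
    with pytest.raises(ValueError):
        mc.gm_hazard(-1.0, 1e-4, 0.1)


def test_gm_survival_closed_form_and_limits():
    a, b = np.exp(-11.5), 0.115
    assert mc.gm_survival(0.0, a, b) == 1.0
    assert mc.gm_survival(80.0, a, b) == pytest.approx(
        np.exp(-(a / b) * (np.exp(b * 80) - 1)), rel=1e-12
    )
    # exponential limit
    assert mc.gm_survival(30.0, 2e-3, 0.0, 1e-3) == pytest.approx(np.exp(-3e-3 * 30))


def test_gm_survival_matches_quadrature(rng):
    """S(x) = exp(-integral of hazard) to 1e-8 for random parameter draws."""
    for _ in range(25):
        a = np.exp(rng.uniform(-16, -7))
        b = rng.uniform(0.05, 0.25)
        m = rng.uniform(0, 5e-3)
        x = rng.uniform(1, 90)
        integral, _ = scipy.integrate.quad(lambda t: mc.gm_hazard(t, a, b, m), 0, x)
        assert mc.gm_survival(x, a, b, m) == pytest.approx(np.exp(-integral), abs=1e-8)


# ------------------------------------------------------------------------- fit_gm
def test_fit_gm_recovers_parameters():
    spec = mc.GenotypeSpec("g", alpha=np.exp(-11.5), beta=0.115, n_vials=40)
    ln_a_err, beta_rel = [], []
    for seed in range(8):
        fit = mc.fit_gm(mc.simulate_gm_deaths(spec, seed=seed))
        ln_a_err.append(abs(np.log(fit.alpha_) + 11.5))
        beta_rel.append(abs(fit.beta_ - 0.115) / 0.115)
    assert np.median(ln_a_err) < 0.5
    assert np.median(beta_rel) < 0.10


def test_fit_gm_exponential_data_drives_beta_to_zero():
    spec = mc.GenotypeSpec("exp", alpha=0.0, beta=0.0, makeham=0.03, n_vials=40)
    dt = mc.simulate_gm_deaths(spec, seed=0)
    fit = mc.fit_gm(dt, include_makeham=False)
    # constant hazard: the Gompertz slope collapses toward the boundary
    assert fit.beta_ < 0.02


def test_fit_gm_mle_dominates_truth_and_coarse_grid():
    spec = mc.GenotypeSpec("g", alpha=np.exp(-12.5), beta=0.15, n_vials=20)
    dt = mc.simulate_gm_deaths(spec, seed=42)
    fit = mc.fit_gm(dt, include_makeham=False)
    ll_hat = fit.log_likelihood_
    assert ll_hat >= gm_interval_loglik(dt, spec.alpha, spec.beta) - 1e-9
    # no coarse lattice point beats the optimizer
    for ln_a in np.linspace(-16, -9, 15):
        for b in np.linspace(0.05, 0.3, 15):
            assert gm_interval_loglik(dt, np.exp(ln_a), b) <= ll_hat + 1e-3


def test_fit_gm_beta_error_shrinks_with_cohort_size():
    """Consistency: median |beta_hat - beta| at n=2000 below that at n=200."""
    errs = {}
    for n_vials, n_label in ((8, 200), (80, 2000)):
        spec = mc.GenotypeSpec("g", alpha=np.exp(-12), beta=0.14, n_vials=n_vials)
        errs[n_label] = np.median(
            [
                abs(mc.fit_gm(mc.simulate_gm_deaths(spec, seed=s), include_makeham=False).beta_ - 0.14)
                for s in range(10)
            ]
        )
    assert errs[2000] < errs[200]


def test_fit_gm_rejects_single_interval():
    dt = DeathTable(
        "one",
        pd.DataFrame(
            {"vial": ["v1"], "interval_start": [10.0], "interval_end": [12.0], "n_dead": [50]}
        ),
    )
    with pytest.raises(ValueError):
        mc.fit_gm(dt)


def test_fit_gm_warns_on_few_deaths():
    dt = DeathTable(
        "tiny",
        pd.DataFrame(
            {
                "vial": ["v1"] * 3,
                "interval_start": [10.0, 20.0, 30.0],
                "interval_end": [12.0, 22.0, 32.0],
                "n_dead": [2, 3, 2],
            }
        ),
    )
    with pytest.warns(UserWarning, match="unreliable"):
        mc.fit_gm(dt)


# -------------------------------------------------------------- restricted mean
def test_km_point_mass_interval_end_convention():
    dt = DeathTable(
        "pm",
        pd.DataFrame(
            {"vial": ["v1"], "interval_start": [10.0], "interval_end": [12.0], "n_dead": [10]}
        ),
    )
    mean, se = mc.km_restricted_mean(dt)
    assert mean == pytest.approx(12.0)
    assert np.isfinite(se)


def test_km_equals_sample_mean_without_censoring():
    spec = mc.GenotypeSpec("g", alpha=np.exp(-11.5), beta=0.115)
    dt = mc.simulate_gm_deaths(spec, seed=5)
    durations, _ = dt.to_events()
    mean, se = mc.km_restricted_mean(dt, tau=durations.max())
    assert mean == pytest.approx(durations.mean(), abs=1e-9)
    # Greenwood area SE matches the classic SEM for complete data
    assert se == pytest.approx(durations.std(ddof=1) / np.sqrt(len(durations)), rel=0.02)


def test_km_with_censoring_matches_hand_enumerated_steps():
    # 6 flies: deaths at 10, 10, 20, 30, 40; one censored at 20 (at risk for
    # the day-20 death, removed afterwards).
    # KM steps: 1 on [0,10); 4/6 on [10,20); 4/6*3/4=1/2 on [20,30);
    # 1/2*1/2=1/4 on [30,40); 0 after.
    dt = DeathTable(
        "hand",
        pd.DataFrame(
            {
                "vial": ["v1"] * 4,
                "interval_start": [8.0, 18.0, 28.0, 38.0],
                "interval_end": [10.0, 20.0, 30.0, 40.0],
                "n_dead": [2, 1, 1, 1],
                "n_censored": [0, 1, 0, 0],
            }
        ),
    )
    mean, _ = mc.km_restricted_mean(dt, tau=40.0)
    expected = 10 * (1.0 + 4 / 6 + 1 / 2 + 1 / 4)
    assert mean == pytest.approx(expected, abs=1e-9)


def test_km_rejects_tau_before_first_event():
    dt = DeathTable(
        "pm",
        pd.DataFrame(
            {"vial": ["v1"], "interval_start": [10.0], "interval_end": [12.0], "n_dead": [5]}
        ),
    )
    with pytest.raises(ValueError):
        mc.km_restricted_mean(dt, tau=5.0)


# ----------------------------------------------------------------------- log-rank
def _table(gid, rows):
    return DeathTable(
        gid,
        pd.DataFrame(rows, columns=["vial", "interval_start", "interval_end", "n_dead"]),
    )


def test_log_rank_identical_tables_gives_zero():
    rows = [("v1", 8.0, 10.0, 5), ("v1", 18.0, 20.0, 5)]
    chi2, df, p = mc.log_rank([_table("a", rows), _table("b", rows)])
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert df == 1
    assert p == pytest.approx(1.0)


def test_log_rank_three_groups_matches_hand_computation():
    """Observed-minus-expected computation on a small 3-group table.

    Groups a/b/c die at distinct times; the chi2 from the explicit O-E table
    (computed below with plain numpy) must match the pooled implementation.
    """
    groups = [
        _table("a", [("v1", 8.0, 10.0, 3), ("v1", 18.0, 20.0, 2)]),
        _table("b", [("v1", 18.0, 20.0, 3), ("v1", 28.0, 30.0, 2)]),
        _table("c", [("v1", 28.0, 30.0, 3), ("v1", 38.0, 40.0, 2)]),
    ]
    chi2, df, _ = mc.log_rank(groups)
    assert df == 2

    # independent hand computation (standard k-sample log-rank)
    durations = np.array([10.0] * 3 + [20.0] * 2 + [20.0] * 3 + [30.0] * 2 + [30.0] * 3 + [40.0] * 2)
    labels = np.array(["a"] * 5 + ["b"] * 5 + ["c"] * 5)
    times = np.unique(durations)
    names = ["a", "b", "c"]
    O = np.zeros(3)
    E = np.zeros(3)
    V = np.zeros((3, 3))
    for t in times:
        at_risk = durations >= t
        dying = durations == t
        n, d = at_risk.sum(), dying.sum()
        for i, g in enumerate(names):
            n_g = (at_risk & (labels == g)).sum()
            O[i] += (dying & (labels == g)).sum()
            E[i] += d * n_g / n
        if n > 1:
            for i, gi in enumerate(names):
                n_i = (at_risk & (labels == gi)).sum()
                for j, gj in enumerate(names):
                    n_j = (at_risk & (labels == gj)).sum()
                    V[i, j] += d * (n - d) / (n - 1) * (n_i / n) * ((i == j) - n_j / n)
    z = (O - E)[:-1]
    expected_chi2 = z @ np.linalg.solve(V[:-1, :-1], z)
    assert chi2 == pytest.approx(expected_chi2, rel=1e-9)


def test_log_rank_invariant_to_vial_partitioning(population):
    _, tables = population
    some = [tables[k] for k in list(tables)[:4]]
    merged = [t.merged_vials() for t in some]
    assert mc.log_rank(some)[0] == pytest.approx(mc.log_rank(merged)[0], rel=1e-12)


def test_log_rank_separates_default_population(population):
    _, tables = population
    chi2, df, p = mc.log_rank(list(tables.values()))
    assert df == len(tables) - 1
    assert p < 1e-10


# -------------------------------------------------- cross-genotype diagnostics
def test_lifespan_variance_model_exact_linear_and_null(rng):
    n = 20
    ln_a = rng.uniform(-16, -9, n)
    beta = rng.uniform(0.1, 0.2, n)
    df = pd.DataFrame(
        {
            "genotype": [f"g{i}" for i in range(n)],
            "ln_alpha": ln_a,
            "beta": beta,
            "mean_lifespan": 5 - 3 * ln_a - 100 * beta,
        }
    )
    assert mc.lifespan_variance_model(df)["adj_r2"] == pytest.approx(1.0, abs=1e-10)
    null_r2 = []
    for _ in range(20):
        df["mean_lifespan"] = rng.permutation(df["mean_lifespan"].to_numpy())
        null_r2.append(mc.lifespan_variance_model(df)["adj_r2"])
    assert abs(np.mean(null_r2)) < 0.15


def test_lifespan_variance_model_on_simulated_population(demo):
    out = mc.lifespan_variance_model(demo)
    assert out["adj_r2"] >= 0.8  # GM parameters explain most lifespan variance


def test_strehler_mildvan_rank_identity():
    df = pd.DataFrame(
        {"genotype": list("abc"), "ln_alpha": [-10.0, -12.0, -14.0], "beta": [0.1, 0.15, 0.2]}
    )
    rho, _ = mc.strehler_mildvan(df)
    assert rho == pytest.approx(-1.0)


def test_strehler_mildvan_recovered_from_coupled_population(demo):
    rho, p = mc.strehler_mildvan(demo)
    assert rho < -0.3 and p < 0.05
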