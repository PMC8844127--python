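"""Elastic-net metabolome age clock, age acceleration, and mortality links.

The clock minimizes

    (1/2N) * sum_i (y_i - b0 - x_i' b)^2
        + lambda2 * [ (1 - lambda1) * ||b||_2^2 / 2 + lambda1 * ||b||_1 ]

over (b0, b), with the intercept never penalized.  lambda1 mixes ridge
(lambda1 = 0) into lasso (lambda1 = 1); lambda1 = lambda2 = 0 is ordinary
least squares.  Hyperparameters are chosen by 5-fold cross-validation inside
repeated 80/20 train/test splits; per-sample predicted ages come from
leave-one-out cross-validation at the consensus pair, and age acceleration
theta = predicted - chronological age is the per-sample clock residual whose
genotype means are associated with demographic parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import ElasticNet
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted, validate_data

from .tables import MetaboliteMatrix


def elastic_net_objective(X, y, intercept, coef, lambda1, lambda2) -> float:
    """The penalized loss evaluated at (intercept, coef)."""
    n = len(y)
    resid = y - intercept - X @ coef
    penalty = lambda2 * (
        (1 - lambda1) * np.sum(coef**2) / 2.0 + lambda1 * np.sum(np.abs(coef))
    )
    return float(np.sum(resid**2) / (2 * n) + penalty)


def _ridge_solve(X, y, lam2_ridge):
    """Closed-form ridge with unpenalized intercept.

    Minimizes (1/2N)||y - b0 - Xb||^2 + (lam2_ridge/2)||b||^2, i.e.
    b = (X_c'X_c + N*lam2_ridge*I)^-1 X_c'y_c on centered data.
    """
    n, p = X.shape
    xm, ym = X.mean(axis=0), y.mean()
    Xc, yc = X - xm, y - ym
    coef = np.linalg.solve(Xc.T @ Xc + n * lam2_ridge * np.eye(p), Xc.T @ yc)
    return ym - xm @ coef, coef


class MetabolomeAgeClock(RegressorMixin, BaseEstimator):
    """Penalized linear age predictor over metabolite profiles.

    Parameters
    ----------
    lambda1 : float in [0, 1]
        Mixing parameter; 0 = ridge, 1 = lasso.
    lambda2 : float >= 0
        Regularization strength; 0 together with lambda1=0 gives OLS.
    max_iter, tol : coordinate-descent controls for the mixed penalty.

    Notes
    -----
    Features enter as-is (samples are already row-standardized upstream); no
    per-feature standardization happens inside the fit.  lambda1 = 0 uses the
    closed-form ridge solution; lambda2 = 0 uses OLS; the mixed penalty uses
    coordinate descent (whose objective is algebraically identical with
    alpha = lambda2, l1_ratio = lambda1).
    """

    def __init__(
        self,
        lambda1: float = 0.0,
        lambda2: float = 1.0,
        max_iter: int = 50_000,
        tol: float = 1e-7,
    ):
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        X, y = validate_data(self, X, y, ensure_all_finite=True, y_numeric=True)
        if not 0.0 <= self.lambda1 <= 1.0:
            raise ValueError("lambda1 must lie in [0, 1]")
        if self.lambda2 < 0:
            raise ValueError("lambda2 must be non-negative")
        if self.lambda2 == 0.0:
            A = np.column_stack([np.ones(len(y)), X])
            beta, *_ = np.linalg.lstsq(A, y, rcond=None)
            self.intercept_, self.coef_ = float(beta[0]), beta[1:]
        elif self.lambda1 == 0.0:
            b0, coef = _ridge_solve(X, y, self.lambda2)
            self.intercept_, self.coef_ = float(b0), coef
        else:
            en = ElasticNet(
                alpha=self.lambda2,
                l1_ratio=self.lambda1,
                fit_intercept=True,
                max_iter=self.max_iter,
                tol=self.tol,
            )
            en.fit(X, y)
            self.intercept_, self.coef_ = float(en.intercept_), en.coef_.copy()
        self.training_loss_ = elastic_net_objective(
            X, y, self.intercept_, self.coef_, self.lambda1, self.lambda2
        )
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.intercept_ + X @ self.coef_


def elastic_net_fit(X, y, lambda1: float, lambda2: float) -> MetabolomeAgeClock:
    """Fit the penalized clock at fixed (lambda1, lambda2) (thin wrapper)."""
    return MetabolomeAgeClock(lambda1=lambda1, lambda2=lambda2).fit(X, y)


def default_lambda2_grid() -> np.ndarray:
    """100 values evenly spaced in [1e-6, 1] plus 1000 in [1, 1000]."""
    return np.unique(np.concatenate([np.linspace(1e-6, 1, 100), np.linspace(1, 1000, 1000)]))


@dataclass
class ClockHyperparams:
    """Tuning design: grids, repeated-split counts, and CV folds."""

    lambda1_grid: tuple = tuple(np.round(np.arange(0, 1.01, 0.1), 1))
    lambda2_grid: np.ndarray = field(default_factory=default_lambda2_grid)
    n_repeats: int = 100
    test_fraction: float = 0.2
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.lambda1_grid) == 0 or len(self.lambda2_grid) == 0:
            raise ValueError("hyperparameter grids must be non-empty")
        l1 = np.asarray(self.lambda1_grid, float)
        if (l1 < 0).any() or (l1 > 1).any():
            raise ValueError("lambda1 values must lie in [0, 1]")
        if (np.asarray(self.lambda2_grid, float) < 0).any():
            raise ValueError("lambda2 values must be non-negative")


def _cv_mse_grid(X, y, folds, lambda1_grid, lambda2_grid):
    """Mean CV squared error for every (lambda1, lambda2) pair.

    Ridge (lambda1=0) is evaluated for the whole lambda2 path per fold from
    one eigendecomposition; other lambda1 values warm-start coordinate
    descent down the lambda2 path.
    """
    l2 = np.asarray(lambda2_grid, float)
    mse = np.zeros((len(lambda1_grid), len(l2)))
    for train, test in folds:
        Xtr, ytr, Xte, yte = X[train], y[train], X[test], y[test]
        n, p = Xtr.shape
        xm, ym = Xtr.mean(axis=0), ytr.mean()
        Xc, yc = Xtr - xm, ytr - ym
        for i, l1 in enumerate(lambda1_grid):
            if l1 == 0.0:
                # eigendecomposition of X'X gives the full ridge path cheaply
                w, V = np.linalg.eigh(Xc.T @ Xc)
                xty = Xc.T @ yc
                vz = V.T @ xty
                for j, lam in enumerate(l2):
                    if lam == 0.0:
                        coef, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
                    else:
                        coef = V @ (vz / (w + n * lam))
                    pred = ym + (Xte - xm) @ coef
                    mse[i, j] += np.mean((yte - pred) ** 2)
            else:
                en = ElasticNet(
                    alpha=1.0, l1_ratio=l1, fit_intercept=True, warm_start=True,
                    max_iter=20_000, tol=1e-5,
                )
                for j in np.argsort(l2)[::-1]:
                    if l2[j] == 0.0:
                        m = MetabolomeAgeClock(lambda1=l1, lambda2=0.0).fit(Xtr, ytr)
                        pred = m.predict(Xte)
                    else:
                        en.set_params(alpha=l2[j])
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            en.fit(Xtr, ytr)
                        pred = en.predict(Xte)
                    mse[i, j] += np.mean((yte - pred) ** 2)
    return mse / len(folds)


@dataclass
class ClockEvaluation:
    """Per-repeat held-out performance and the consensus hyperparameters."""

    per_repeat: pd.DataFrame
    consensus_lambda1: float
    consensus_lambda2: float
    mean_cv_mse: np.ndarray


def tune_and_evaluate(mat: MetaboliteMatrix, hp: ClockHyperparams) -> ClockEvaluation:
    """Repeated 80/20 splits with grid search by 5-fold CV inside training.

    Each repeat selects its own (lambda1, lambda2) by minimum mean CV squared
    error, refits on the whole training set, and reports held-out R^2.  The
    consensus pair minimizes the CV error averaged over all repeats.
    """
    if mat.n_samples < 30:
        raise ValueError("need at least 30 samples to tune the clock")
    X = mat.values.to_numpy(dtype=float)
    y = mat.samples["age_day"].to_numpy(dtype=float)
    rng = np.random.default_rng(hp.seed)
    n_test = max(int(round(hp.test_fraction * len(y))), 1)
    l2 = np.asarray(hp.lambda2_grid, float)
    total_mse = np.zeros((len(hp.lambda1_grid), len(l2)))
    records = []
    for rep in range(hp.n_repeats):
        perm = rng.permutation(len(y))
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        kf = KFold(hp.cv_folds, shuffle=True, random_state=int(rng.integers(2**31)))
        folds = list(kf.split(train_idx))
        folds = [(train_idx[a], train_idx[b]) for a, b in folds]
        mse = _cv_mse_grid(X, y, folds, hp.lambda1_grid, l2)
        total_mse += mse
        i, j = np.unravel_index(np.argmin(mse), mse.shape)
        model = MetabolomeAgeClock(lambda1=hp.lambda1_grid[i], lambda2=l2[j]).fit(
            X[train_idx], y[train_idx]
        )
        records.append(
            {
                "repeat": rep,
                "lambda1": hp.lambda1_grid[i],
                "lambda2": l2[j],
                "test_r2": r2_score(y[test_idx], model.predict(X[test_idx])),
            }
        )
    mean_mse = total_mse / hp.n_repeats
    i, j = np.unravel_index(np.argmin(mean_mse), mean_mse.shape)
    return ClockEvaluation(
        per_repeat=pd.DataFrame(records),
        consensus_lambda1=float(hp.lambda1_grid[i]),
        consensus_lambda2=float(l2[j]),
        mean_cv_mse=mean_mse,
    )


def loocv_predict(
    mat: MetaboliteMatrix, lambda1: float, lambda2: float
) -> pd.DataFrame:
    """Leave-one-out predicted age per sample at fixed hyperparameters.

    Every sample is predicted by a model fitted on all other samples, so no
    sample influences its own prediction.  Returns the age-acceleration table
    (sample_id, genotype_id, age_day, predicted_age, theta).
    """
    X = mat.values.to_numpy(dtype=float)
    y = mat.samples["age_day"].to_numpy(dtype=float)
    preds = np.empty(len(y))
    for i in range(len(y)):
        keep = np.arange(len(y)) != i
        model = MetabolomeAgeClock(lambda1=lambda1, lambda2=lambda2).fit(X[keep], y[keep])
        preds[i] = model.predict(X[i][None, :])[0]
    out = mat.samples[["genotype_id", "age_day"]].copy()
    out.insert(0, "sample_id", mat.values.index)
    out = out.reset_index(drop=True)
    out["predicted_age"] = preds
    return age_acceleration(out)


def age_acceleration(predictions: pd.DataFrame) -> pd.DataFrame:
    """theta = predicted - chronological age, per sample."""
    out = predictions.copy()
    out["theta"] = out["predicted_age"] - out["age_day"]
    return out


def genotype_age_acceleration(aa: pd.DataFrame) -> pd.DataFrame:
    """Genotype x age means of theta."""
    return (
        aa.groupby(["genotype_id", "age_day"], as_index=False)["theta"]
        .mean()
        .rename(columns={"theta": "mean_theta"})
    )


def aa_demography_assoc(
    aa: pd.DataFrame, summaries: pd.DataFrame, at_age: float
) -> pd.DataFrame:
    """Associate genotype-mean age acceleration at one age with demography.

    For each parameter (mean lifespan, ln alpha, beta, and the model-based
    mid-age hazards) reports the linear-model slope and p of phi_k on theta,
    and Spearman's rho and p.  Negative theta-lifespan correlation means
    biologically-old genotypes die sooner.
    """
    means = genotype_age_acceleration(aa)
    sel = means[means["age_day"] == at_age].set_index("genotype_id")["mean_theta"]
    if sel.empty:
        raise ValueError(f"age {at_age} not present in the age-acceleration table")
    demo = summaries.set_index("genotype")
    params = [c for c in ("mean_lifespan", "ln_alpha", "beta") if c in demo.columns]
    params += [c for c in demo.columns if c.startswith("hazard_d")]
    common = sel.index.intersection(demo.index)
    if len(common) < 5:
        raise ValueError("fewer than 5 genotypes shared with demography")
    theta = sel.loc[common].to_numpy(float)
    rows = []
    for pname in params:
        phi = demo.loc[common, pname].to_numpy(float)
        if np.ptp(theta) == 0 or np.ptp(phi) == 0:
            rows.append(
                {"parameter": pname, "age_day": at_age, "slope": np.nan,
                 "p_lm": np.nan, "rho": np.nan, "p_rho": np.nan}
            )
            continue
        lin = scipy.stats.linregress(theta, phi)
        rho, p_rho = scipy.stats.spearmanr(theta, phi)
        rows.append(
            {
                "parameter": pname,
                "age_day": at_age,
                "slope": float(lin.slope),
                "p_lm": float(lin.pvalue),
                "rho": float(rho),
                "p_rho": float(p_rho),
            }
        )
    return pd.DataFrame(rows)
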