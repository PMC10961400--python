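"""PWV prediction models: participant-level split, repeated cross-validation,
LASSO / random-forest / linear regression, importances and test metrics.

The protocol mirrors a small-cohort workflow: an 80/20 participant split,
hyperparameters chosen by lowest mean RMSE under repeated k-fold
cross-validation on the training set (10-fold, 50 repeats by default), the
winning configuration refit on the full training set, and evaluation on the
held-out participants. All preprocessing statistics (median imputation,
centering/scaling) are learned on the training split only and frozen, so no
test information leaks into tuning. Both R^2 conventions are reported:
1 - SS_res/SS_tot is the headline (``r2``), the squared Pearson correlation
is ``r2_corr``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.inspection import permutation_importance
from sklearn.linear_model import Lasso, LinearRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GridSearchCV, RepeatedKFold, cross_validate

from . import config as _cfg
from .cohort_stats import AgreementReport, Scaler, bland_altman

ALGORITHMS = ("lasso", "random_forest", "linear")


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: algorithm, feature set, outcome and seed."""

    algorithm: str
    feature_set: str = "updated"
    include_npat: bool = False
    outcome: str = "cfpwv"
    seed: int = 0
    named_subset: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")


@dataclass
class FittedModel:
    spec: ModelSpec
    estimator: object
    scaler: Scaler
    medians: pd.Series
    feature_names: list[str]
    resample_rmse: float
    resample_r2: float
    best_params: dict

    def _prepare(self, X: pd.DataFrame) -> pd.DataFrame:
        X = X[self.feature_names].fillna(self.medians)
        if not self.feature_names:
            return X
        return self.scaler.transform(X)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict(self._prepare(X))


@dataclass
class ModelReport:
    """Fitted-model metrics on the outcome's native scale (m/s)."""

    spec: ModelSpec
    resample_rmse: float
    resample_r2: float
    test_rmse: float
    test_r2: float
    test_r2_corr: float
    importances: dict[str, float]
    predictions: pd.Series
    agreement: AgreementReport
    best_params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "algorithm": self.spec.algorithm,
            "feature_set": self.spec.feature_set,
            "outcome": self.spec.outcome,
            "resample_rmse": self.resample_rmse,
            "resample_r2": self.resample_r2,
            "test_rmse": self.test_rmse,
            "test_r2": self.test_r2,
            "test_r2_corr": self.test_r2_corr,
            "best_params": self.best_params,
            "bland_altman": {
                "bias": self.agreement.bias,
                "loa_low": self.agreement.loa_low,
                "loa_high": self.agreement.loa_high,
            },
            "importances": self.importances,
        }


def split(
    panel: pd.DataFrame,
    outcome: pd.Series,
    prop: float = 0.8,
    seed: int = 0,
) -> tuple[tuple[pd.DataFrame, pd.Series], tuple[pd.DataFrame, pd.Series]]:
    """Random participant-level train/test split.

    ``n_train = round(prop * n)`` (banker's rounding as in Python); train and
    test are disjoint and exhaustive. ``prop`` must leave at least one
    participant on each side.
    """
    n = len(panel)
    if not panel.index.equals(outcome.index):
        raise ValueError("panel and outcome must share the same index")
    n_train = round(prop * n)
    if n_train < 1 or n_train >= n:
        raise ValueError(f"prop={prop} leaves an empty train or test set for n={n}")
    if n < 10:
        warnings.warn(f"n={n} participants makes the split degenerate")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train_idx = panel.index[np.sort(order[:n_train])]
    test_idx = panel.index[np.sort(order[n_train:])]
    return (
        (panel.loc[train_idx], outcome.loc[train_idx]),
        (panel.loc[test_idx], outcome.loc[test_idx]),
    )


class _MeanPredictor:
    """Intercept-only fallback when no informative features survive."""

    def fit(self, X, y):
        self.mean_ = float(np.mean(y))
        self.coef_ = np.zeros(X.shape[1] if hasattr(X, "shape") else 0)
        return self

    def predict(self, X):
        return np.full(len(X), self.mean_)


def _drop_and_impute(
    X: pd.DataFrame, max_missing_frac: float
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    frac = X.isna().mean()
    keep = list(frac[frac <= max_missing_frac].index)
    dropped = list(frac[frac > max_missing_frac].index)
    medians = X[keep].median()
    return X[keep].fillna(medians), medians, dropped


def tune_fit(
    X_train: pd.DataFrame,
    y_train: pd.Series,
    spec: ModelSpec,
    cfg: dict | None = None,
    cv_repeats: int | None = None,
) -> FittedModel:
    """Select hyperparameters by repeated k-fold CV and refit on full train.

    Features missing for more than the configured fraction of training
    participants are dropped; the remainder are median-imputed and
    centered/scaled with training statistics. ``cv_repeats`` overrides the
    configured repeat count (useful for quick runs).
    """
    cfg = cfg or _cfg.default_config()
    mcfg = cfg["model"]
    if y_train.std(ddof=0) == 0:
        raise ValueError("constant outcome; nothing to fit")
    X_imp, medians, _dropped = _drop_and_impute(X_train, mcfg["max_missing_frac"])
    # guard columns that became constant within the training split
    const = X_imp.columns[X_imp.std(ddof=0) == 0]
    X_imp = X_imp.drop(columns=const)
    medians = medians.drop(index=const)
    if X_imp.shape[1] == 0:
        est = _MeanPredictor().fit(X_imp, y_train)
        return FittedModel(
            spec=spec, estimator=est, scaler=Scaler(), medians=medians,
            feature_names=[], resample_rmse=float(y_train.std(ddof=0)),
            resample_r2=0.0, best_params={},
        )
    scaler = Scaler().fit(X_imp)
    Xs = scaler.transform(X_imp)

    folds = min(mcfg["cv_folds"], len(Xs))
    repeats = cv_repeats if cv_repeats is not None else mcfg["cv_repeats"]
    cv = RepeatedKFold(n_splits=folds, n_repeats=repeats, random_state=spec.seed)
    scoring = {"rmse": "neg_root_mean_squared_error", "r2": "r2"}

    if spec.algorithm == "lasso":
        alphas = np.logspace(-3, 1, int(mcfg["lasso_alphas"]))
        grid = GridSearchCV(
            Lasso(max_iter=50_000),
            {"alpha": alphas},
            scoring=scoring,
            refit="rmse",
            cv=cv,
            n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            grid.fit(Xs, y_train)
        best = grid.best_index_
        est = grid.best_estimator_
        res_rmse = -grid.cv_results_["mean_test_rmse"][best]
        res_r2 = grid.cv_results_["mean_test_r2"][best]
        params = grid.best_params_
    elif spec.algorithm == "random_forest":
        base = RandomForestRegressor(
            n_estimators=int(mcfg["rf_n_trees"]), random_state=spec.seed, n_jobs=1
        )
        grid = GridSearchCV(
            base,
            {
                "max_features": list(mcfg["rf_mtry_grid"]),
                "min_samples_leaf": list(mcfg["rf_min_leaf_grid"]),
            },
            scoring=scoring,
            refit="rmse",
            cv=cv,
            n_jobs=1,
        )
        grid.fit(Xs, y_train)
        best = grid.best_index_
        est = grid.best_estimator_
        res_rmse = -grid.cv_results_["mean_test_rmse"][best]
        res_r2 = grid.cv_results_["mean_test_r2"][best]
        params = grid.best_params_
    else:  # linear
        est = LinearRegression()
        scores = cross_validate(est, Xs, y_train, scoring=scoring, cv=cv, n_jobs=1)
        res_rmse = -scores["test_rmse"].mean()
        res_r2 = scores["test_r2"].mean()
        est.fit(Xs, y_train)
        params = {}

    return FittedModel(
        spec=spec,
        estimator=est,
        scaler=scaler,
        medians=medians,
        feature_names=list(Xs.columns),
        resample_rmse=float(res_rmse),
        resample_r2=float(res_r2),
        best_params=params,
    )


def importance(
    fitted: FittedModel,
    X_train: pd.DataFrame | None = None,
    y_train: pd.Series | None = None,
) -> dict[str, float]:
    """Variable importance on a relative scale with the top feature at 100.

    LASSO: absolute standardized coefficients (exact zeros for dropped
    features). Random forest: permutation importance on the training data
    (negatives clipped to zero). Plain linear models return the coefficient
    table instead, unscaled.
    """
    est = fitted.estimator
    if fitted.spec.algorithm == "lasso":
        scores = np.abs(est.coef_)
    elif fitted.spec.algorithm == "random_forest":
        if X_train is None or y_train is None:
            raise ValueError("random-forest importance needs the training data")
        Xs = fitted._prepare(X_train)
        perm = permutation_importance(
            est, Xs, y_train, n_repeats=10, random_state=fitted.spec.seed, n_jobs=1
        )
        scores = np.clip(perm.importances_mean, 0.0, None)
    else:
        return dict(zip(fitted.feature_names, map(float, est.coef_)))
    top = scores.max()
    if top > 0:
        scores = scores / top * 100.0
    return dict(zip(fitted.feature_names, map(float, scores)))


def evaluate(
    fitted: FittedModel, X_test: pd.DataFrame, y_test: pd.Series,
    importances: dict[str, float] | None = None,
) -> ModelReport:
    """Test-set RMSE, both R^2 conventions and Bland-Altman agreement."""
    if len(X_test) == 0:
        raise ValueError("empty test set")
    pred = fitted.predict(X_test)
    err = pred - y_test.to_numpy()
    rmse = float(np.sqrt(np.mean(err**2)))
    ss_tot = float(np.sum((y_test - y_test.mean()) ** 2))
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot if ss_tot > 0 else np.nan
    if np.std(pred) > 0 and y_test.std() > 0:
        r2_corr = float(np.corrcoef(pred, y_test)[0, 1] ** 2)
    else:
        r2_corr = np.nan
    agreement = bland_altman(y_test.to_numpy(), pred)
    return ModelReport(
        spec=fitted.spec,
        resample_rmse=fitted.resample_rmse,
        resample_r2=fitted.resample_r2,
        test_rmse=rmse,
        test_r2=r2,
        test_r2_corr=r2_corr,
        importances=importances or {},
        predictions=pd.Series(pred, index=y_test.index, name="prediction"),
        agreement=agreement,
        best_params=fitted.best_params,
    )
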