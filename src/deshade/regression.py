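"""Leaf-nitrogen prediction models on sensitive vegetation-index features.

Four estimators — multiple linear regression (MLR), principal component
regression (PCR), partial least squares regression (PLSR) and RBF-kernel
support vector machine regression (SVMR) — fitted on features combined
across pixel classes, evaluated on a held-out split with R², RMSE and MAE.

Features are standardised before PCR/PLSR/SVMR; MLR runs on raw features
(ordinary least squares is scale-equivariant).  Hyperparameters are chosen
by k-fold cross-validation on the training split only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .stats import SensitiveSet

__all__ = [
    "FeatureMatrix",
    "ModelReport",
    "combine_features",
    "split_samples",
    "evaluate",
    "fit_predict",
    "METHODS",
]

METHODS = ("MLR", "PCR", "PLSR", "SVMR")


@dataclass
class FeatureMatrix:
    """Samples × (class, index) feature block aligned with an LNC target.

    ``X`` holds raw (unstandardised) feature values; the per-column
    standardisation parameters actually applied by the scale-sensitive
    estimators are stored in ``scaling`` as (mean, sd) series.
    """

    X: pd.DataFrame
    y: pd.Series
    scaling: tuple[pd.Series, pd.Series] = field(init=False)

    def __post_init__(self) -> None:
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing cells")
        if not self.X.index.equals(self.y.index):
            raise ValueError("features and target are not aligned by sample_id")
        sd = self.X.std(ddof=0).replace(0.0, 1.0)
        self.scaling = (self.X.mean(), sd)

    @property
    def n_samples(self) -> int:
        return len(self.X)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass
class ModelReport:
    """Held-out performance of one fitted model."""

    method: str
    hyperparameters: dict
    r2: float
    rmse: float
    mae: float
    split: str
    seed: int
    n_train: int
    n_test: int
    predictions: pd.DataFrame | None = None

    def summary(self) -> str:
        hp = ", ".join(f"{k}={v}" for k, v in self.hyperparameters.items()) or "none"
        return (
            f"{self.method} (train n={self.n_train}, test n={self.n_test}, "
            f"{self.split}, seed={self.seed})\n"
            f"  hyperparameters: {hp}\n"
            f"  R2 = {self.r2:.3f}  RMSE = {self.rmse:.3f}  MAE = {self.mae:.3f}"
        )

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "hyperparameters": self.hyperparameters,
            "r2": self.r2,
            "rmse": self.rmse,
            "mae": self.mae,
            "split": self.split,
            "seed": self.seed,
            "n_train": self.n_train,
            "n_test": self.n_test,
        }


def combine_features(
    vitables: dict[str, pd.DataFrame],
    sensitive: SensitiveSet,
    mode: str = "concat",
    k: int | None = None,
    seed: int = 0,
) -> FeatureMatrix:
    """Combine per-class VI tables into one feature matrix.

    ``concat`` takes every sensitive (class, index) column; ``random_subset``
    draws ``k`` of them with a seeded generator.  Rows with any missing cell
    (a sample whose ROI lacked some class) are dropped.  Column names are
    ``"<class>:<index>"``.
    """
    blocks = []
    for cls, table in vitables.items():
        names = sensitive.per_class.get(str(cls), [])
        if not names:
            continue
        block = table[names].copy()
        block.columns = [f"{cls}:{n}" for n in names]
        blocks.append(block)
    if not blocks:
        raise ValueError("no sensitive columns selected from any class")
    X = pd.concat(blocks, axis=1, join="inner")

    lnc_parts = [t["lnc"] for t in vitables.values() if "lnc" in t.columns]
    if not lnc_parts:
        raise ValueError("VI tables carry no lnc column")
    y = pd.concat(lnc_parts).groupby(level=0).first().reindex(X.index)

    keep = X.notna().all(axis=1) & y.notna()
    X, y = X.loc[keep], y.loc[keep]

    if mode == "random_subset":
        if not k or k < 1:
            raise ValueError("random_subset mode requires k >= 1")
        rng = np.random.default_rng(seed)
        cols = rng.choice(X.columns, size=min(k, X.shape[1]), replace=False)
        X = X[list(cols)]
    elif mode != "concat":
        raise ValueError(f"unknown mode {mode!r}")
    return FeatureMatrix(X, y.rename("lnc"))


def split_samples(
    n: int, test_fraction: float = 0.3, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive, seeded train/test index split."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = max(1, int(round(n * test_fraction)))
    return np.sort(order[n_test:]), np.sort(order[:n_test])


def evaluate(pred, obs) -> tuple[float, float, float]:
    """(R², RMSE, MAE).  R² = 1 - SS_res/SS_tot, deliberately unclamped."""
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if pred.shape != obs.shape:
        raise ValueError("pred and obs must have the same length")
    resid = obs - pred
    ss_res = float((resid**2).sum())
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    rmse = float(np.sqrt((resid**2).mean()))
    mae = float(np.abs(resid).mean())
    return r2, rmse, mae


def _build_estimator(method: str, n_train: int, n_features: int, seed: int, cv: int):
    """Estimator + CV hyperparameter grid for one method."""
    kfold = KFold(n_splits=cv, shuffle=True, random_state=seed)
    max_comp = max(1, min(10, n_features, n_train - int(np.ceil(n_train / cv)) - 1))
    comps = list(range(1, max_comp + 1))
    if method == "MLR":
        return LinearRegression(), None, None
    if method == "PCR":
        pipe = Pipeline(
            [("scale", StandardScaler()), ("pca", PCA()), ("ols", LinearRegression())]
        )
        return pipe, {"pca__n_components": comps}, kfold
    if method == "PLSR":
        pipe = Pipeline([("scale", StandardScaler()), ("pls", PLSRegression(scale=False))])
        return pipe, {"pls__n_components": comps}, kfold
    if method == "SVMR":
        pipe = Pipeline([("scale", StandardScaler()), ("svr", SVR(kernel="rbf"))])
        grid = {
            "svr__C": [1.0, 10.0, 100.0],
            "svr__gamma": ["scale", 0.01, 0.1],
            "svr__epsilon": [0.01, 0.1, 0.5],
        }
        return pipe, grid, kfold
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def fit_predict(
    features: FeatureMatrix,
    method: str,
    seed: int = 0,
    test_fraction: float = 0.3,
    cv: int = 5,
    hyper_grid: dict | None = None,
    keep_predictions: bool = False,
) -> ModelReport:
    """Fit one model on a seeded train split and evaluate on the held-out test.

    MLR requires more training rows than features (otherwise the normal
    equations are rank-deficient; use PCR or PLSR for wide feature sets).
    All fitters are deterministic given (features, seed, grid).
    """
    X = features.X.values
    y = features.y.values
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    train, test = split_samples(len(y), test_fraction, seed)
    if method == "MLR" and len(train) <= X.shape[1]:
        raise ValueError(
            f"MLR needs more training rows ({len(train)}) than features "
            f"({X.shape[1]}); use PCR or PLSR for wide feature sets"
        )
    n_splits = min(cv, len(train))
    if n_splits < 2 or len(train) // n_splits < 1:
        raise ValueError("cross-validation folds would be smaller than 2 samples")

    estimator, grid, kfold = _build_estimator(method, len(train), X.shape[1], seed, n_splits)
    if hyper_grid is not None:
        grid = hyper_grid
    if grid:
        search = GridSearchCV(estimator, grid, cv=kfold, scoring="neg_mean_squared_error")
        search.fit(X[train], y[train])
        model = search.best_estimator_
        hyper = {k.split("__")[-1]: v for k, v in search.best_params_.items()}
    else:
        model = estimator.fit(X[train], y[train])
        hyper = {}
    pred = np.asarray(model.predict(X[test])).ravel()
    r2, rmse, mae = evaluate(pred, y[test])
    predictions = None
    if keep_predictions:
        predictions = pd.DataFrame(
            {"sample_id": features.X.index[test], "observed": y[test], "predicted": pred}
        )
    return ModelReport(
        method=method,
        hyperparameters=hyper,
        r2=r2,
        rmse=rmse,
        mae=mae,
        split=f"{1 - test_fraction:.0%}/{test_fraction:.0%} hold-out, {n_splits}-fold CV",
        seed=seed,
        n_train=len(train),
        n_test=len(test),
        predictions=predictions,
    )
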