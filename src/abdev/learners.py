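"""Learner registry: the three regression algorithms behind the platform

models (elastic net, RBF-kernel SVM, random forest), each with its
hyperparameter grid tuned by an inner cross-validation on the training
rows only. Grids live in ``data/platforms.yaml`` and can be overridden.

The registry is a plug-in point: :func:`register` adds further algorithms
without touching the training code.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.svm import SVR

ALGORITHM_ORDER = ("elastic_net", "svm_rbf", "random_forest")

_REGISTRY: dict[str, Callable] = {}


def register(name: str, fit_fn: Callable) -> None:
    """Register a learner: fit_fn(X, y, grid, seed) -> fitted estimator."""
    _REGISTRY[name] = fit_fn


def fit_learner(name: str, X: np.ndarray, y: np.ndarray, grid: dict,
                seed: int = 0):
    """Fit a registered learner on (scaled) training data."""
    if name not in _REGISTRY:
        raise KeyError(f"unknown algorithm {name!r}; "
                       f"registered: {sorted(_REGISTRY)}")
    return _REGISTRY[name](np.asarray(X, float), np.asarray(y, float),
                           grid or {}, seed)


def _inner_cv(grid: dict, n: int, seed: int):
    folds = min(int(grid.get("inner_folds", 3)), max(2, n // 4))
    return KFold(n_splits=folds, shuffle=True, random_state=seed)


def _fit_elastic_net(X, y, grid, seed):
    l1_ratios = grid.get("l1_ratio", [0.1, 0.5, 0.9])
    n_alphas = int(grid.get("n_alphas", 20))
    alphas = np.logspace(np.log10(grid.get("alpha_min", 1e-4)),
                         np.log10(grid.get("alpha_max", 10.0)), n_alphas)
    search = GridSearchCV(
        ElasticNet(max_iter=10000),
        {"alpha": alphas, "l1_ratio": l1_ratios},
        cv=_inner_cv(grid, len(y), seed),
        scoring="neg_mean_absolute_error",
        n_jobs=1,
    )
    search.fit(X, y)
    return search.best_estimator_


def median_heuristic_gamma(X: np.ndarray) -> float:
    """RBF kernel width from the median pairwise squared distance."""
    if len(X) > 400:
        X = X[:: len(X) // 400 + 1]
    d2 = pdist(X, "sqeuclidean")
    med = np.median(d2[d2 > 0]) if np.any(d2 > 0) else 1.0
    return 1.0 / med


def _fit_svm_rbf(X, y, grid, seed):
    costs = grid.get("cost", [0.25, 0.5, 1.0, 2.0, 4.0])
    factors = grid.get("gamma_factors", [0.5, 1.0, 2.0])
    g0 = median_heuristic_gamma(X)
    search = GridSearchCV(
        SVR(kernel="rbf"),
        {"C": costs, "gamma": [g0 * f for f in factors]},
        cv=_inner_cv(grid, len(y), seed),
        scoring="neg_mean_absolute_error",
        n_jobs=1,
    )
    search.fit(X, y)
    return search.best_estimator_


def _fit_random_forest(X, y, grid, seed):
    model = RandomForestRegressor(
        n_estimators=int(grid.get("n_estimators", 500)),
        max_features=grid.get("max_features", 1.0 / 3.0),
        random_state=seed,
        n_jobs=1,
    )
    model.fit(X, y)
    return model


register("elastic_net", _fit_elastic_net)
register("svm_rbf", _fit_svm_rbf)
register("random_forest", _fit_random_forest)
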