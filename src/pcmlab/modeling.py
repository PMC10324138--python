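"""Base learners on shared cross-validation folds.

The contribution here is the protocol, not the learner internals: all three
algorithms (random forest, RBF-kernel support vector regression, gradient
boosting) are tuned over explicit hyperparameter grids using one shared fold
assignment, selected by minimum cross-validated RMSE computed from pooled
out-of-fold predictions, then refit on the full training set. The shared
folds are what make the out-of-fold prediction columns combinable by the
ensemble stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.svm import SVR

__all__ = [
    "CVScheme",
    "TrainedModel",
    "make_cv_folds",
    "default_grid",
    "train_model",
    "predict",
    "variable_importance",
    "ALGORITHMS",
]

ALGORITHMS = ("RF", "SVM-RBF", "GBM")


@dataclass(frozen=True)
class CVScheme:
    """A k-fold partition of the training rows, shared by all base learners."""

    k: int
    assignment: np.ndarray  # fold id per training row, values 0..k-1
    seed: int

    def __post_init__(self) -> None:
        folds = np.unique(self.assignment)
        if not np.array_equal(folds, np.arange(self.k)):
            raise ValueError("assignment must use every fold id 0..k-1")

    @property
    def n(self) -> int:
        return len(self.assignment)


def make_cv_folds(n_train: int, k: int = 10, seed: int = 0) -> CVScheme:
    """Seeded k-fold assignment with fold sizes differing by at most one."""
    if k > n_train:
        raise ValueError(f"k={k} exceeds n_train={n_train}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_train)
    assignment = np.empty(n_train, dtype=int)
    # round-robin over a shuffled order gives near-equal fold sizes
    assignment[order] = np.arange(n_train) % k
    return CVScheme(k=k, assignment=assignment, seed=seed)


@dataclass
class TrainedModel:
    """A tuned base learner with its grid-search record and OOF predictions."""

    algorithm: str
    grid: list[dict[str, Any]]
    chosen: dict[str, Any]
    oof_predictions: np.ndarray  # out-of-fold prediction per training row
    cv_rmse: float
    cv_rmse_by_point: list[float]
    estimator: Any  # fitted sklearn predictor
    scheme: CVScheme
    feature_names: list[str]
    seed: int

    def manifest(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "chosen": self.chosen,
            "cv_rmse": self.cv_rmse,
            "seed": self.seed,
            "k": self.scheme.k,
            "fold_seed": self.scheme.seed,
            "n_features": len(self.feature_names),
        }


# ---------------------------------------------------------------------------
# grids and estimator construction
# ---------------------------------------------------------------------------

def default_grid(algorithm: str, n_features: int) -> list[dict[str, Any]]:
    """Default hyperparameter grid for an algorithm, bracketing field practice.

    RF searches mtry (features per split) over {p/3, 128, 256, p/2} capped at
    p; SVM-RBF searches the kernel bandwidth sigma and cost C around
    (0.01, 3); GBM holds 500 trees, depth 25 and 20 minimum node observations
    constant and searches the learning rate over {0.04, 0.08, 0.12, 0.16}.
    """
    p = n_features
    if algorithm == "RF":
        mtry = sorted({min(p, m) for m in (max(1, p // 3), 128, 256, max(1, p // 2))})
        return [{"mtry": m} for m in mtry]
    if algorithm == "SVM-RBF":
        return [
            {"sigma": s, "C": c}
            for s in (0.001, 0.01, 0.1)
            for c in (1.0, 3.0, 10.0)
        ]
    if algorithm == "GBM":
        return [
            {
                "n_trees": 500,
                "interaction_depth": 25,
                "shrinkage": s,
                "n_minobsinnode": 20,
            }
            for s in (0.04, 0.08, 0.12, 0.16)
        ]
    raise ValueError(f"unknown algorithm {algorithm!r}; supported: {ALGORITHMS}")


def _make_estimator(algorithm: str, params: dict[str, Any], n_features: int, seed: int):
    if algorithm == "RF":
        return RandomForestRegressor(
            n_estimators=params.get("n_trees", 500),
            max_features=min(int(params["mtry"]), n_features),
            random_state=seed,
            n_jobs=1,
        )
    if algorithm == "SVM-RBF":
        # kernlab-style sigma: k(x, y) = exp(-sigma * ||x - y||^2)
        return SVR(kernel="rbf", gamma=float(params["sigma"]), C=float(params["C"]))
    if algorithm == "GBM":
        return GradientBoostingRegressor(
            n_estimators=int(params.get("n_trees", 500)),
            max_depth=int(params.get("interaction_depth", 25)),
            learning_rate=float(params["shrinkage"]),
            min_samples_leaf=int(params.get("n_minobsinnode", 20)),
            random_state=seed,
        )
    raise ValueError(f"unknown algorithm {algorithm!r}; supported: {ALGORITHMS}")


# ---------------------------------------------------------------------------
# training protocol
# ---------------------------------------------------------------------------

def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((a - b) ** 2)))


def train_model(
    algorithm: str,
    X_train: pd.DataFrame,
    y_train: np.ndarray | pd.Series,
    grid: Sequence[dict[str, Any]] | None = None,
    scheme: CVScheme | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Grid search by shared-fold CV RMSE, then refit at the winning point.

    For every grid point, out-of-fold predictions are assembled under the
    shared :class:`CVScheme` (the model for fold f is trained on all other
    folds and predicts fold f). The winner is the point with the smallest
    RMSE of pooled OOF predictions against the observed responses; ties break
    toward the earlier grid point. The returned model carries the winning
    OOF prediction vector for downstream ensembling.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; supported: {ALGORITHMS}")
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float)
    if np.isnan(X).any():
        raise ValueError("X_train contains NA; impute before training")
    n, p = X.shape
    if scheme is None:
        scheme = make_cv_folds(n, seed=seed)
    if scheme.n != n:
        raise ValueError("CV scheme row count does not match X_train")
    grid = list(grid) if grid is not None else default_grid(algorithm, p)
    if not grid:
        raise ValueError("empty hyperparameter grid")

    oof_by_point: list[np.ndarray] = []
    rmse_by_point: list[float] = []
    for params in grid:
        oof = np.empty(n)
        for f in range(scheme.k):
            hold = scheme.assignment == f
            est = _make_estimator(algorithm, params, p, seed)
            est.fit(X[~hold], y[~hold])
            oof[hold] = est.predict(X[hold])
        oof_by_point.append(oof)
        rmse_by_point.append(_rmse(oof, y))

    best = int(np.argmin(rmse_by_point))
    final = _make_estimator(algorithm, grid[best], p, seed)
    final.fit(X, y)

    names = (
        list(X_train.columns)
        if isinstance(X_train, pd.DataFrame)
        else [f"x{i}" for i in range(p)]
    )
    return TrainedModel(
        algorithm=algorithm,
        grid=grid,
        chosen=grid[best],
        oof_predictions=oof_by_point[best],
        cv_rmse=rmse_by_point[best],
        cv_rmse_by_point=rmse_by_point,
        estimator=final,
        scheme=scheme,
        feature_names=names,
        seed=seed,
    )


def predict(model: TrainedModel, X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Predict responses for new rows, refusing silent column misalignment."""
    if isinstance(X, pd.DataFrame):
        if list(X.columns) != model.feature_names:
            missing = [c for c in model.feature_names if c not in X.columns]
            extra = [c for c in X.columns if c not in model.feature_names]
            raise ValueError(
                "feature columns do not match training columns "
                f"(missing: {missing or 'none'}, extra: {extra or 'none'}, "
                "order must match)"
            )
        X = X.to_numpy(float)
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(model.feature_names):
        raise ValueError(
            f"expected {len(model.feature_names)} features, got {X.shape[1]}"
        )
    out = np.asarray(model.estimator.predict(X), dtype=float)
    if not np.isfinite(out).all():
        raise ValueError("model produced non-finite predictions")
    return out


def variable_importance(
    model: TrainedModel,
    top_n: int = 21,
    X: pd.DataFrame | np.ndarray | None = None,
    y: np.ndarray | None = None,
    seed: int = 0,
) -> list[tuple[str, float]]:
    """Top descriptors ranked by importance (nonincreasing, nonnegative).

    Tree models expose impurity-based importances directly; SVR falls back to
    permutation importance, which requires the data it should be scored on.
    ``top_n`` beyond the feature count truncates.
    """
    est = model.estimator
    if hasattr(est, "feature_importances_"):
        scores = np.asarray(est.feature_importances_, dtype=float)
    else:
        if X is None or y is None:
            raise ValueError(
                f"{model.algorithm} has no intrinsic importance; pass X and y "
                "for permutation importance"
            )
        Xa = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        result = permutation_importance(
            est, Xa, np.asarray(y, float), n_repeats=5, random_state=seed
        )
        scores = np.maximum(result.importances_mean, 0.0)
    top_n = min(top_n, len(scores))
    order = np.argsort(scores)[::-1][:top_n]
    return [(model.feature_names[i], float(scores[i])) for i in order]
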