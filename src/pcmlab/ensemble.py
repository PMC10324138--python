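"""Ensembles of base learners over out-of-fold predictions.

Two combination strategies: greedy integer-count weight selection (the
ensemble weight for each model is incremented whenever doing so reduces the
RMSE of the count-weighted mean of out-of-fold prediction columns against the
observed responses) and stacking, where a meta-model is fit on the
out-of-fold prediction columns. Both are trained strictly on out-of-fold
predictions — never resubstitution predictions — so the ensemble's CV error
is honest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Literal

import numpy as np
from sklearn.linear_model import ElasticNetCV, LinearRegression
from sklearn.svm import SVR

__all__ = [
    "EnsembleWeights",
    "StackingModel",
    "greedy_ensemble",
    "stack_ensemble",
    "ensemble_predict",
    "META_KINDS",
]

META_KINDS = ("linear", "elastic-net", "SVM-linear", "SVM-RBF")


@dataclass
class EnsembleWeights:
    """Normalized nonnegative per-model weights plus the greedy iteration log.

    ``iteration_log`` rows are (iteration, model index incremented, resulting
    CV RMSE); the logged RMSE is nonincreasing because increments are only
    committed when they strictly improve it.
    """

    weights: np.ndarray
    counts: np.ndarray
    cv_rmse: float
    iteration_log: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")
        if (self.weights < 0).any():
            raise ValueError("weights must be nonnegative")

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "counts": self.counts.tolist(),
            "cv_rmse": self.cv_rmse,
            "iteration_log": [list(t) for t in self.iteration_log],
        }


@dataclass
class StackingModel:
    """A meta-model fit on base-model out-of-fold prediction columns."""

    meta_kind: str
    estimator: Any
    n_models: int

    @property
    def coefficients(self) -> np.ndarray | None:
        """Relative model contributions, for linear meta-kinds."""
        coef = getattr(self.estimator, "coef_", None)
        return None if coef is None else np.ravel(np.asarray(coef, dtype=float))


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((a - b) ** 2)))


def greedy_ensemble(
    oof_matrix: np.ndarray,
    y_train: np.ndarray,
    n_iter: int = 1000,
    strict_improvement: bool = True,
) -> EnsembleWeights:
    """Greedy integer-count ensemble selection on out-of-fold predictions.

    All model counts start at zero. At each of ``n_iter`` iterations every
    candidate single-count increment is scored by the RMSE of the resulting
    count-weighted mean of OOF columns against ``y_train``; the best
    increment is committed only if it strictly reduces the current RMSE,
    with ties between candidates broken toward the lowest model index. Final
    counts are normalized to weights.

    When no single increment improves, a one-count step (of size
    1/(total+1) in weight space) is simply too coarse; the iteration then
    doubles every count, which leaves the weights and the RMSE untouched but
    halves the step size, so later iterations can refine. This keeps the
    committed-iteration RMSE log strictly decreasing while letting the
    procedure converge to the optimum of the RMSE (a convex function of the
    weights) over the weight simplex. Refinement stops once the total count
    exceeds ``10**9`` (weight resolution far below any reported precision),
    at which point the procedure has converged and returns early.

    ``strict_improvement=False`` gives the unconditional Caruana-style
    variant that always commits the best candidate; its logged RMSE need not
    be monotone and no refinement is performed.
    """
    oof = np.asarray(oof_matrix, dtype=float)
    y = np.asarray(y_train, dtype=float)
    if oof.ndim != 2 or oof.shape[1] == 0:
        raise ValueError("oof_matrix must be 2-D with at least one model column")
    if np.isnan(oof).any():
        raise ValueError("oof_matrix contains NA")
    n, m = oof.shape
    if len(y) != n:
        raise ValueError("y_train length does not match oof_matrix rows")

    counts = np.zeros(m, dtype=int)
    current_sum = np.zeros(n)
    current_rmse = np.inf
    log: list[tuple[int, int, float]] = []
    for it in range(n_iter):
        candidate_rmse = np.array(
            [_rmse((current_sum + oof[:, j]) / (counts.sum() + 1), y) for j in range(m)]
        )
        j = int(np.argmin(candidate_rmse))  # argmin takes the lowest index on ties
        if strict_improvement and not candidate_rmse[j] < current_rmse:
            if counts.sum() > 10**9:
                break  # converged: steps below any meaningful resolution
            counts *= 2  # refine: same weights and RMSE, half the step size
            current_sum *= 2
            continue
        counts[j] += 1
        current_sum += oof[:, j]
        current_rmse = candidate_rmse[j]
        log.append((it, j, current_rmse))

    if counts.sum() == 0:  # cannot happen under strict improvement with n_iter >= 1
        counts[0] = 1
        current_rmse = _rmse(oof[:, 0], y)
    weights = counts / counts.sum()
    return EnsembleWeights(
        weights=weights, counts=counts, cv_rmse=current_rmse, iteration_log=log
    )


def _make_meta(meta_kind: str):
    if meta_kind == "linear":
        return LinearRegression()
    if meta_kind == "elastic-net":
        return ElasticNetCV(l1_ratio=[0.1, 0.5, 0.9], cv=5, random_state=0)
    if meta_kind == "SVM-linear":
        return SVR(kernel="linear")
    if meta_kind == "SVM-RBF":
        return SVR(kernel="rbf")
    raise ValueError(f"unknown meta_kind {meta_kind!r}; supported: {META_KINDS}")


def stack_ensemble(
    oof_matrix: np.ndarray,
    y_train: np.ndarray,
    meta_kind: Literal["linear", "elastic-net", "SVM-linear", "SVM-RBF"] = "linear",
) -> StackingModel:
    """Fit a stacking meta-model on the out-of-fold prediction columns."""
    oof = np.asarray(oof_matrix, dtype=float)
    y = np.asarray(y_train, dtype=float)
    if oof.ndim != 2 or oof.shape[1] == 0:
        raise ValueError("oof_matrix must be 2-D with at least one model column")
    if np.isnan(oof).any():
        raise ValueError("oof_matrix contains NA")
    est = _make_meta(meta_kind)
    est.fit(oof, y)
    return StackingModel(meta_kind=meta_kind, estimator=est, n_models=oof.shape[1])


def ensemble_predict(
    combiner: EnsembleWeights | StackingModel, base_predictions: np.ndarray
) -> np.ndarray:
    """Combine base-model prediction columns for new rows.

    ``base_predictions`` columns must align with the training-time model
    order; a column-count mismatch raises rather than misaligning silently.
    """
    P = np.asarray(base_predictions, dtype=float)
    if P.ndim != 2:
        raise ValueError("base_predictions must be 2-D (rows x models)")
    if isinstance(combiner, EnsembleWeights):
        if P.shape[1] != len(combiner.weights):
            raise ValueError(
                f"expected {len(combiner.weights)} model columns, got {P.shape[1]}"
            )
        return P @ combiner.weights
    if P.shape[1] != combiner.n_models:
        raise ValueError(
            f"expected {combiner.n_models} model columns, got {P.shape[1]}"
        )
    return np.asarray(combiner.estimator.predict(P), dtype=float)
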