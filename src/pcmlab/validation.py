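"""External-validation statistics, performance bounds, applicability domain.

Implements the QSAR/PCM validation suite: the squared-correlation and
through-origin metrics behind the Golbraikh-Tropsha acceptability criteria,
the three external predictivity coefficients Q2_F1/F2/F3, the theoretical
maximum-performance distributions implied by experimental uncertainty in the
response, and the leverage-based applicability domain summarized by a
Williams plot (leverage h against standardized residual s).

Conventions made explicit here because the field is loose about them:
``r2`` denotes the squared Pearson correlation between observed and
predicted (the usual "R2_test"), while ``q2_f2`` is the coefficient of
determination; both are reported so the distinction is visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ValidationReport",
    "TheoreticalBounds",
    "ADReport",
    "regression_metrics",
    "gt_criteria",
    "theoretical_bounds",
    "leverage_ad",
    "DEFAULT_SIGMA",
]

# default experimental uncertainty of heterogeneous public IC50 data, pIC50 units
DEFAULT_SIGMA = 0.68


@dataclass
class ValidationReport:
    """The full external/internal validation metric suite for one model."""

    r2_test: float
    r2_0_test: float
    k_slope: float
    q2_f1: float
    q2_f2: float
    q2_f3: float
    rmse_test: float
    mae: float
    r2_cv: float | None = None
    rmse_cv: float | None = None
    criterion_ratio: float | None = None
    criteria_pass: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


@dataclass
class TheoreticalBounds:
    """Distributions of the best R2_0 / lowest RMSE reachable given noise sigma."""

    sigma: float
    n_sim: int
    r2_0_max_mean: float
    r2_0_max_q05: float
    r2_0_max_q95: float
    rmse_min_mean: float
    rmse_min_q05: float
    rmse_min_q95: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class ADReport:
    """Leverage-based applicability domain (Williams plot data)."""

    leverage: np.ndarray
    std_residual: np.ndarray
    h_star: float
    flags: list[str]  # per row: "influential" | "outlier" | "inside"
    train_leverage_sum: float
    design_rank: int

    def flag_counts(self) -> dict[str, int]:
        out = {"influential": 0, "outlier": 0, "inside": 0}
        for f in self.flags:
            out[f] += 1
        return out


# ---------------------------------------------------------------------------
# metric suite
# ---------------------------------------------------------------------------

def regression_metrics(
    y_obs: np.ndarray,
    y_pred: np.ndarray,
    y_train_mean: float,
    train_variance: float,
) -> ValidationReport:
    """External-validation metric suite for one observed/predicted vector pair.

    Definitions (sums over the test set):

    - ``r2_test``: squared Pearson correlation of observed and predicted.
    - ``k_slope``: through-origin regression slope of observed on predicted,
      k = sum(y_obs * y_pred) / sum(y_pred^2).
    - ``r2_0_test``: 1 - sum((y_obs - k*y_pred)^2) / sum((y_obs - mean(y_obs))^2).
    - ``q2_f1`` uses the training mean as reference: 1 - PRESS / sum((y_obs - y_train_mean)^2).
    - ``q2_f2`` uses the test mean: 1 - PRESS / sum((y_obs - mean(y_obs))^2).
    - ``q2_f3``: 1 - (PRESS / n_test) / train_variance, with ``train_variance``
      the training response variance about its mean (population denominator).
    - ``rmse_test``, ``mae``: the usual error magnitudes.
    """
    yo = np.asarray(y_obs, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yo.shape != yp.shape or yo.ndim != 1:
        raise ValueError("y_obs and y_pred must be 1-D vectors of equal length")
    n = len(yo)
    if n < 3:
        raise ValueError("need at least 3 observations")
    ss_obs = float(np.sum((yo - yo.mean()) ** 2))
    if ss_obs == 0:
        raise ValueError("y_obs has zero variance")

    press = float(np.sum((yo - yp) ** 2))
    rmse = float(np.sqrt(press / n))
    mae = float(np.mean(np.abs(yo - yp)))

    sp = float(np.sum((yp - yp.mean()) ** 2))
    if sp == 0:
        r2 = 0.0  # constant predictions carry no correlation signal
    else:
        r = float(np.corrcoef(yo, yp)[0, 1])
        r2 = r * r

    sum_p2 = float(np.sum(yp**2))
    k = float(np.sum(yo * yp) / sum_p2) if sum_p2 > 0 else np.nan
    r2_0 = 1.0 - float(np.sum((yo - k * yp) ** 2)) / ss_obs if np.isfinite(k) else np.nan

    q2_f1 = 1.0 - press / float(np.sum((yo - y_train_mean) ** 2))
    q2_f2 = 1.0 - press / ss_obs
    q2_f3 = 1.0 - (press / n) / float(train_variance)

    report = ValidationReport(
        r2_test=r2,
        r2_0_test=r2_0,
        k_slope=k,
        q2_f1=q2_f1,
        q2_f2=q2_f2,
        q2_f3=q2_f3,
        rmse_test=rmse,
        mae=mae,
    )
    gt_criteria(report)
    return report


def gt_criteria(report: ValidationReport) -> dict:
    """Golbraikh-Tropsha acceptability flags, stored on the report.

    Criteria: (R2_test - R2_0_test) / R2_test < 0.1, and 0.85 <= k <= 1.15.
    An undefined ratio (R2_test = 0) fails with a recorded reason.
    """
    flags: dict = {}
    if report.r2_test == 0 or not np.isfinite(report.r2_test):
        report.criterion_ratio = np.nan
        flags["r2_ratio"] = False
        flags["r2_ratio_reason"] = "R2_test is zero; ratio undefined"
    else:
        ratio = (report.r2_test - report.r2_0_test) / report.r2_test
        report.criterion_ratio = float(ratio)
        flags["r2_ratio"] = bool(ratio < 0.1)
    flags["k_slope"] = bool(0.85 <= report.k_slope <= 1.15) if np.isfinite(report.k_slope) else False
    flags["overall"] = bool(flags["r2_ratio"] and flags["k_slope"])
    report.criteria_pass = flags
    return flags


def internal_metrics(y_train: np.ndarray, oof_predictions: np.ndarray) -> tuple[float, float]:
    """R2_cv and RMSE_cv from pooled out-of-fold predictions vs observed."""
    y = np.asarray(y_train, dtype=float)
    oof = np.asarray(oof_predictions, dtype=float)
    r = float(np.corrcoef(y, oof)[0, 1])
    rmse = float(np.sqrt(np.mean((y - oof) ** 2)))
    return r * r, rmse


# ---------------------------------------------------------------------------
# theoretical performance bounds
# ---------------------------------------------------------------------------

def theoretical_bounds(
    y_test: np.ndarray,
    sigma: float = DEFAULT_SIGMA,
    n_sim: int = 1000,
    seed: int = 0,
) -> TheoreticalBounds:
    """Best-case R2_0 / worst-case-floor RMSE given response uncertainty.

    A perfect model can at best predict the noiseless response, so its
    observed performance is bounded by the measurement noise: each replicate
    simulates pseudo-predictions y~ = y_test + N(0, sigma^2) and records
    r2_0(y_test, y~) and rmse(y_test, y~). The returned summaries describe
    the distribution of the maximum reachable R2_0 and minimum reachable
    RMSE. With sigma = 0 the bounds are exactly 1 and 0.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    y = np.asarray(y_test, dtype=float)
    n = len(y)
    ss_obs = float(np.sum((y - y.mean()) ** 2))
    rng = np.random.default_rng(seed)
    r2_0s = np.empty(n_sim)
    rmses = np.empty(n_sim)
    for i in range(n_sim):
        yt = y + rng.normal(0.0, sigma, size=n)
        sum_p2 = float(np.sum(yt**2))
        k = float(np.sum(y * yt) / sum_p2) if sum_p2 > 0 else 1.0
        r2_0s[i] = 1.0 - float(np.sum((y - k * yt) ** 2)) / ss_obs
        rmses[i] = float(np.sqrt(np.mean((y - yt) ** 2)))
    return TheoreticalBounds(
        sigma=float(sigma),
        n_sim=n_sim,
        r2_0_max_mean=float(r2_0s.mean()),
        r2_0_max_q05=float(np.quantile(r2_0s, 0.05)),
        r2_0_max_q95=float(np.quantile(r2_0s, 0.95)),
        rmse_min_mean=float(rmses.mean()),
        rmse_min_q05=float(np.quantile(rmses, 0.05)),
        rmse_min_q95=float(np.quantile(rmses, 0.95)),
    )


# ---------------------------------------------------------------------------
# applicability domain
# ---------------------------------------------------------------------------

def leverage_ad(
    X_train_scaled: np.ndarray,
    X_query_scaled: np.ndarray,
    residuals_query: np.ndarray,
    training_residuals: np.ndarray | None = None,
) -> ADReport:
    """Leverage / standardized-residual applicability domain.

    Leverage of a query row x is h = x (X'X)^-1 x' over the training design
    matrix X (pseudo-inverse when X is rank deficient; the rank is recorded).
    The warning threshold is h* = 3p/n with p the descriptor count and n the
    training size. Standardized residuals are the query residuals divided by
    the SD of the training residuals (sample SD; the query residuals are used
    when no training residuals are given). Flags: ``outlier`` iff |s| > 3;
    ``influential`` iff h > h* and |s| <= 3; else ``inside``.
    """
    Xt = np.asarray(X_train_scaled, dtype=float)
    Xq = np.asarray(X_query_scaled, dtype=float)
    res = np.asarray(residuals_query, dtype=float)
    if Xt.ndim != 2 or Xq.ndim != 2 or Xt.shape[1] != Xq.shape[1]:
        raise ValueError("X_train and X_query must be 2-D with equal column counts")
    if len(res) != len(Xq):
        raise ValueError("residuals_query length must match X_query rows")

    n, p = Xt.shape
    # SVD-based hat values: one rank decision governs leverage and trace,
    # so sum(train leverages) = rank(X) holds to machine precision even for
    # ill-conditioned or rank-deficient designs
    U, S, Vt = np.linalg.svd(Xt, full_matrices=False)
    tol = S.max(initial=0.0) * max(n, p) * np.finfo(float).eps
    rank = int(np.sum(S > tol))
    Vr = Vt[:rank].T
    Sr = S[:rank]
    leverage = np.sum(((Xq @ Vr) / Sr) ** 2, axis=1)
    train_leverage = np.sum(U[:, :rank] ** 2, axis=1)
    h_star = 3.0 * p / n

    ref = res if training_residuals is None else np.asarray(training_residuals, float)
    sd = float(np.std(ref, ddof=1))
    s = res / sd if sd > 0 else np.zeros_like(res)

    flags = []
    for h, si in zip(leverage, s):
        if abs(si) > 3:
            flags.append("outlier")
        elif h > h_star:
            flags.append("influential")
        else:
            flags.append("inside")
    return ADReport(
        leverage=np.asarray(leverage),
        std_residual=np.asarray(s),
        h_star=h_star,
        flags=flags,
        train_leverage_sum=float(train_leverage.sum()),
        design_rank=rank,
    )
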