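"""Penalized log-linear AFT regression and censored-sample loss/imputation.

All computation lives on the log-time scale: the model is
``log t = intercept + x'beta + eps``.  Censored samples enter through a
constrained loss — a prediction below the (log) censoring time is infeasible
and receives a large finite sentinel loss; otherwise the loss is squared
error against the current pseudo log-time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cox import _cd_solve, km_estimator
from .data_model import SurvivalDataset
from .penalties import PenaltySpec

__all__ = [
    "AftFit",
    "INFEASIBLE_LOSS",
    "km_conditional_mean_impute",
    "censored_loss",
    "fit_penalized_aft",
    "cv_aft_lambda",
]

# Sentinel for censoring-constraint violations: finite so that age-parameter
# arithmetic stays well-defined, but far above any attainable squared loss.
INFEASIBLE_LOSS = 1e12


@dataclass
class AftFit:
    """Fitted penalized AFT model (log-time scale)."""

    intercept: float
    beta: np.ndarray
    support: np.ndarray
    converged: bool
    n_iterations: int = 0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.support = np.asarray(self.support, dtype=int)
        if not np.array_equal(np.sort(self.support), np.flatnonzero(self.beta)):
            raise ValueError("support must index exactly the nonzero entries of beta")

    def predict_log_time(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.intercept + X @ self.beta


def km_conditional_mean_impute(data: SurvivalDataset) -> np.ndarray:
    """Initial pseudo log-times for the censored samples of ``data``.

    For a censored sample with censoring time ``c`` the imputed time is the
    Kaplan-Meier conditional mean ``E[T | T > c] = c + (int_c^inf S dt)/S(c)``
    with the step-function KM curve.  If the curve does not reach zero the
    largest observed time is treated as an event for the tail mass (Efron
    tail convention).  Returns log imputed times aligned with the censored
    samples in their original order.
    """
    if data.n_events < 1:
        raise ValueError("cannot form a Kaplan-Meier curve without events")
    time, status = data.time.copy(), data.status.copy()
    t_max = time.max()
    if status[time == t_max].max() == 0:
        # Efron tail: force the curve to zero at the largest observed time
        i_max = int(np.argmax(time))
        status[i_max] = 1
    km = km_estimator(time, status)
    # step-function integral of S on [c, inf): S is piecewise constant,
    # dropping at each event time, and 0 beyond the last one
    et, sp = km.event_times, km.survival_prob
    cens_idx = np.flatnonzero(data.status == 0)
    out = np.empty(cens_idx.size)
    for k, j in enumerate(cens_idx):
        c = data.time[j]
        s_c = float(km.survival_at(c)[0])
        if s_c <= 0.0 or c >= et[-1]:
            warnings.warn(
                f"censoring time {c} at/after the last event time; imputing c*(1+1e-6)",
                RuntimeWarning,
                stacklevel=2,
            )
            out[k] = np.log(c * (1.0 + 1e-6))
            continue
        # knots of S to the right of c
        knots = np.concatenate([[c], et[et > c]])
        levels = np.concatenate([[s_c], sp[et > c]])  # S on [knots[i], knots[i+1])
        integral = float(np.sum(np.diff(knots) * levels[:-1]))
        imputed = c + integral / s_c
        out[k] = np.log(imputed)
    return out


def censored_loss(pseudo_log_time: float, censor_log_time: float, predicted: float) -> float:
    """Constrained squared loss for one censored sample (log-time scale).

    Returns :data:`INFEASIBLE_LOSS` when the prediction falls below the log
    censoring time (the imputed survival time must be at least the censoring
    time); otherwise ``(pseudo_log_time - predicted)**2``.
    """
    if predicted < censor_log_time:
        return INFEASIBLE_LOSS
    return float((pseudo_log_time - predicted) ** 2)


def censored_losses(pseudo_log_time, censor_log_time, predicted) -> np.ndarray:
    """Vectorized :func:`censored_loss`."""
    y = np.asarray(pseudo_log_time, dtype=float)
    c = np.asarray(censor_log_time, dtype=float)
    f = np.asarray(predicted, dtype=float)
    return np.where(f < c, INFEASIBLE_LOSS, (y - f) ** 2)


def fit_penalized_aft(
    X: np.ndarray,
    y: np.ndarray,
    spec: PenaltySpec,
    max_iter: int = 1000,
    tol: float = 1e-7,
    beta_init: np.ndarray | None = None,
) -> AftFit:
    """Coordinate-descent minimizer of ``sum (y - b0 - x'beta)^2 / (2m) + penalty``.

    The intercept is unpenalized (handled by centering); ``X`` is expected to
    be standardized for the penalty to be comparable across genes.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    m, p = X.shape
    if m < 2:
        raise ValueError(f"need at least 2 samples to fit, got {m}")
    if spec.lam is None:
        raise ValueError("PenaltySpec.lam is unresolved; select it (e.g. cv_aft_lambda) first")
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = np.asfortranarray(X - x_mean)
    qc = y - y_mean
    h = np.full(m, 1.0 / m)
    beta = np.zeros(p) if beta_init is None else np.asarray(beta_init, dtype=float).copy()
    sweeps = _cd_solve(Xc, h, qc, beta, spec.lam, spec.gamma, spec.mix, spec.fam_code, tol, max_iter)
    converged = sweeps < max_iter
    if not converged:
        warnings.warn("penalized AFT did not converge", RuntimeWarning, stacklevel=2)
    intercept = float(y_mean - x_mean @ beta)
    return AftFit(
        intercept=intercept,
        beta=beta,
        support=np.flatnonzero(beta),
        converged=converged,
        n_iterations=int(sweeps),
    )


def aft_lambda_max(X: np.ndarray, y: np.ndarray, spec: PenaltySpec) -> float:
    """Smallest lambda making all AFT coefficients zero (centered gradient bound)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    m = X.shape[0]
    Xc = X - X.mean(axis=0)
    lmax = float(np.max(np.abs(Xc.T @ (y - y.mean()))) / m)
    if spec.family == "elastic_net":
        lmax /= spec.mix
    return lmax


def cv_aft_lambda(
    X: np.ndarray,
    y: np.ndarray,
    spec: PenaltySpec,
    n_folds: int = 5,
    n_lambdas: int = 30,
    lambda_min_ratio: float = 0.01,
    seed: int = 0,
) -> float:
    """K-fold cross-validated prediction MSE over a log-spaced lambda path."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    m = X.shape[0]
    n_folds = min(n_folds, m)
    lmax = aft_lambda_max(X, y, spec)
    if lmax <= 0:
        return 1e-12
    lambdas = np.exp(np.linspace(np.log(lmax), np.log(lmax * lambda_min_ratio), n_lambdas))
    rng = np.random.default_rng(seed)
    folds = rng.permutation(m) % n_folds
    cv_mse = np.zeros(n_lambdas)
    for k in range(n_folds):
        tr, te = folds != k, folds == k
        if tr.sum() < 2 or te.sum() == 0:
            continue
        Xtr, ytr = X[tr], y[tr]
        x_mean, y_mean = Xtr.mean(axis=0), ytr.mean()
        Xc = np.asfortranarray(Xtr - x_mean)
        qc = ytr - y_mean
        h = np.full(Xtr.shape[0], 1.0 / Xtr.shape[0])
        beta = np.zeros(X.shape[1])
        for i, lam in enumerate(lambdas):
            _cd_solve(Xc, h, qc, beta, lam, spec.gamma, spec.mix, spec.fam_code, 1e-6, 500)
            pred = y_mean + (X[te] - x_mean) @ beta
            cv_mse[i] += float(np.sum((y[te] - pred) ** 2))
    return float(lambdas[int(np.argmin(cv_mse))])
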