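"""Self-paced AFT: alternating optimization over coefficients, binary sample
weights, pseudo-labels, and an increasing age parameter.

Each censored sample carries a binary weight ``v_j`` and a pseudo log-time
``y_j``.  The alternation is: fit the penalized AFT model on the labeled
samples plus the currently selected censored samples; score every censored
sample with the constrained loss; re-select samples whose loss is at most the
age parameter; refresh pseudo-labels of selected samples with the model
prediction; enlarge the age parameter.  With the hard regularizer
``f(v, age) = -age * v`` the weight update is the closed-form threshold rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .aft import AftFit, censored_losses, fit_penalized_aft, km_conditional_mean_impute
from .data_model import SurvivalDataset
from .penalties import PenaltySpec

__all__ = [
    "SPState",
    "SPConfig",
    "update_weights",
    "update_pseudo_labels",
    "schedule_age",
    "fit_sp_aft",
]

_AGE_EPS = 1e-12


@dataclass
class SPConfig:
    """Pace-control parameters of the self-paced alternation."""

    age_init_quantile: float = 0.5
    age_growth: float = 1.3
    max_rounds: int = 20
    tol: float = 1e-4

    def __post_init__(self) -> None:
        if not 0 < self.age_init_quantile < 1:
            raise ValueError("age_init_quantile must be in (0, 1)")
        if not self.age_growth > 1:
            raise ValueError("age_growth must be > 1")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be positive")
        if not self.tol > 0:
            raise ValueError("tol must be positive")


@dataclass
class SPState:
    """Per-censored-sample weights and pseudo-labels plus the age parameter."""

    weights: np.ndarray  # binary, one per censored sample
    pseudo_log_time: np.ndarray
    age: float = 0.0
    round: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights)
        self.pseudo_log_time = np.asarray(self.pseudo_log_time, dtype=float)
        if not np.all(np.isin(self.weights, (0, 1))):
            raise ValueError("weights must be binary")
        self.weights = self.weights.astype(int)
        if self.weights.shape != self.pseudo_log_time.shape:
            raise ValueError("weights and pseudo_log_time must be aligned")
        if not np.all(np.isfinite(self.pseudo_log_time)):
            raise ValueError("pseudo_log_time must be finite")


def update_weights(losses, age: float) -> np.ndarray:
    """Closed-form weight update: ``v_j = 1`` iff ``loss_j <= age``."""
    if not age > 0:
        raise ValueError("age must be positive")
    losses = np.asarray(losses, dtype=float)
    return (losses <= age).astype(int)


def update_pseudo_labels(state: SPState, predictions) -> SPState:
    """Refresh pseudo log-times with the model prediction where ``v_j = 1``."""
    predictions = np.asarray(predictions, dtype=float)
    if predictions.shape != state.pseudo_log_time.shape:
        raise ValueError("predictions must align with the censored samples")
    y = np.where(state.weights == 1, predictions, state.pseudo_log_time)
    return SPState(weights=state.weights.copy(), pseudo_log_time=y, age=state.age, round=state.round)


def schedule_age(state: SPState, losses, config: SPConfig) -> float:
    """First round: a quantile of the finite losses; afterwards geometric growth."""
    if state.round < 1:
        raise ValueError("schedule_age is defined from round 1 onward")
    if state.round == 1:
        losses = np.asarray(losses, dtype=float)
        finite = losses[losses < 1e11]
        if finite.size == 0:
            warnings.warn(
                "no finite censored losses; age set to a minimal positive value",
                RuntimeWarning,
                stacklevel=2,
            )
            return _AGE_EPS
        return max(float(np.quantile(finite, config.age_init_quantile)), _AGE_EPS)
    new_age = config.age_growth * state.age
    return max(new_age, state.age)


def fit_sp_aft(
    labeled: SurvivalDataset,
    censored: SurvivalDataset,
    penalty: PenaltySpec,
    config: SPConfig | None = None,
    use_spl: bool = True,
    trace: list | None = None,
) -> tuple[AftFit, SPState]:
    """Self-paced penalized AFT on a labeled set plus censored candidates.

    With an empty censored set this reduces exactly to
    :func:`spaft.aft.fit_penalized_aft` on the labeled samples.  With
    ``use_spl=False`` (the no-SPL semi-supervised ablation) every censored
    sample keeps weight 1 throughout the alternation and only
    constraint-violating samples (prediction below the log censoring time)
    are zeroed out at termination.
    """
    if config is None:
        config = SPConfig()
    if labeled.n < 2:
        raise ValueError("need at least 2 labeled samples")
    y_lab = np.log(labeled.time)
    m = censored.n if censored.X.size else 0
    if m == 0:
        fit = fit_penalized_aft(labeled.X, y_lab, penalty)
        return fit, SPState(weights=np.zeros(0, dtype=int), pseudo_log_time=np.zeros(0), age=0.0, round=0)

    # initialization: KM conditional-mean pseudo-labels, all-one weights
    combined = SurvivalDataset(
        X=np.vstack([labeled.X, censored.X]),
        time=np.concatenate([labeled.time, censored.time]),
        status=np.concatenate([np.ones(labeled.n, dtype=int), np.zeros(m, dtype=int)]),
        sample_ids=list(labeled.sample_ids) + list(censored.sample_ids),
        gene_ids=list(labeled.gene_ids),
    )
    pseudo = km_conditional_mean_impute(combined)
    state = SPState(weights=np.ones(m, dtype=int), pseudo_log_time=pseudo, age=0.0, round=0)
    log_c = np.log(censored.time)

    beta_prev = None
    fit = None
    converged = False
    for rnd in range(1, config.max_rounds + 1):
        state.round = rnd
        sel = np.flatnonzero(state.weights == 1)
        X_fit = np.vstack([labeled.X, censored.X[sel]])
        y_fit = np.concatenate([y_lab, state.pseudo_log_time[sel]])
        fit = fit_penalized_aft(X_fit, y_fit, penalty, beta_init=beta_prev)
        preds = fit.predict_log_time(censored.X)
        losses = censored_losses(state.pseudo_log_time, log_c, preds)
        state.age = schedule_age(state, losses, config)
        if use_spl:
            new_w = update_weights(losses, state.age)
        else:
            new_w = np.ones(m, dtype=int)
        weights_unchanged = np.array_equal(new_w, state.weights)
        state.weights = new_w
        state = update_pseudo_labels(state, preds)
        state.round = rnd
        if trace is not None:
            trace.append(
                {
                    "round": rnd,
                    "intercept": fit.intercept,
                    "beta": fit.beta.copy(),
                    "weights": state.weights.copy(),
                    "pseudo_log_time": state.pseudo_log_time.copy(),
                    "losses": losses.copy(),
                    "age": state.age,
                }
            )
        if beta_prev is not None and weights_unchanged:
            if np.max(np.abs(fit.beta - beta_prev)) < config.tol:
                converged = True
                break
        beta_prev = fit.beta.copy()
    if not converged:
        warnings.warn(
            f"SP-AFT alternation did not converge in {config.max_rounds} rounds",
            RuntimeWarning,
            stacklevel=2,
        )
    if not use_spl:
        # the ablation dismisses constraint violators only at termination
        preds = fit.predict_log_time(censored.X)
        state.weights = (preds >= log_c).astype(int)
    return fit, state
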