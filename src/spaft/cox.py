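"""Penalized Cox proportional-hazards fitting, risk stratification, Kaplan-Meier.

The partial likelihood uses risk sets ``R_i = {j : t_j >= t_i}`` with the
Breslow convention for ties.  Fitting is coordinate descent on an iteratively
reweighted least-squares (quadratic) approximation of the negative partial
log-likelihood, with the penalty applied through the scalar thresholding
operators of :mod:`spaft.penalties`.  Only the linear predictor matters
downstream, so the baseline hazard is never estimated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .data_model import SurvivalDataset
from .penalties import PenaltySpec, _threshold

__all__ = [
    "CoxFit",
    "RiskGroups",
    "KMCurve",
    "neg_partial_loglik",
    "cox_gradient",
    "fit_penalized_cox",
    "cv_cox_lambda",
    "prognostic_index",
    "classify_risk",
    "km_estimator",
]

_HESS_FLOOR = 1e-9


@dataclass
class CoxFit:
    """Result of a penalized Cox fit (coefficients on the standardized scale)."""

    beta: np.ndarray
    support: np.ndarray
    lam_used: float
    n_iterations: int
    converged: bool
    partial_loglik: float

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.support = np.asarray(self.support, dtype=int)
        if not np.array_equal(np.sort(self.support), np.flatnonzero(self.beta)):
            raise ValueError("support must index exactly the nonzero entries of beta")
        if not np.isfinite(self.partial_loglik):
            raise ValueError("partial_loglik must be finite")


@dataclass
class RiskGroups:
    """High/low risk labels from a median split of the prognostic index."""

    labels: np.ndarray  # array of "high"/"low"
    threshold: float


@dataclass
class KMCurve:
    """Kaplan-Meier product-limit curve evaluated at the distinct event times."""

    event_times: np.ndarray
    survival_prob: np.ndarray

    def survival_at(self, t) -> np.ndarray:
        """Right-continuous step-function evaluation S(t)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.event_times, t, side="right")
        s = np.concatenate([[1.0], self.survival_prob])
        return s[idx]


def _risk_set_terms(time, status, eta):
    """Negative partial log-likelihood and its gradient/Hessian diagonal in eta.

    Breslow ties; risk set is {j : t_j >= t_i}.  Returns (nll, grad, hess)
    where grad/hess are with respect to the per-sample linear predictor.
    """
    time = np.asarray(time, dtype=float)
    status = np.asarray(status)
    eta = np.asarray(eta, dtype=float)
    n = time.size
    order = np.argsort(time, kind="stable")
    t_s, d_s, e_s = time[order], status[order], eta[order]
    m = e_s.max()
    theta = np.exp(e_s - m)
    # reverse cumulative sum of theta; tie groups share the sum taken at the
    # first index of the group (all tied samples are in each other's risk set)
    rev = np.cumsum(theta[::-1])[::-1]
    new_group = np.empty(n, dtype=bool)
    new_group[0] = True
    new_group[1:] = t_s[1:] != t_s[:-1]
    group_id = np.cumsum(new_group) - 1
    first_idx = np.flatnonzero(new_group)
    first_of_group = first_idx[group_id]
    S = rev[first_of_group]  # risk sum (centered scale) per sample
    ev = d_s == 1
    nll = -float(np.sum(e_s[ev] - (np.log(S[ev]) + m)))
    # cumulative hazard increments at event times (Breslow)
    a = np.zeros(n)  # d_e / S_e contribution at each event sample
    a[ev] = 1.0 / S[ev]
    b = np.zeros(n)
    b[ev] = 1.0 / S[ev] ** 2
    # A_k = sum over events with t_e <= t_k ; with ties, all events in the tie
    # group of t_k are included (they have t_e == t_k <= t_k)
    csum_a = np.cumsum(a)
    csum_b = np.cumsum(b)
    last_of_group = np.append(first_idx[1:] - 1, n - 1)[group_id]
    A = csum_a[last_of_group]
    B = csum_b[last_of_group]
    grad_s = -d_s + theta * A
    hess_s = theta * A - theta**2 * B
    grad = np.empty(n)
    hess = np.empty(n)
    grad[order] = grad_s
    hess[order] = hess_s
    return nll, grad, np.maximum(hess, 0.0)


def neg_partial_loglik(beta, data: SurvivalDataset) -> float:
    """Negative Breslow partial log-likelihood at ``beta``."""
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta contains non-finite values")
    if beta.shape[0] != data.p:
        raise ValueError(f"beta has length {beta.shape[0]}, expected p={data.p}")
    nll, _, _ = _risk_set_terms(data.time, data.status, data.X @ beta)
    return nll


def cox_gradient(beta, data: SurvivalDataset) -> np.ndarray:
    """Gradient of the negative partial log-likelihood with respect to beta."""
    beta = np.asarray(beta, dtype=float)
    _, g_eta, _ = _risk_set_terms(data.time, data.status, data.X @ beta)
    return data.X.T @ g_eta


@njit(cache=True)
def _cd_solve(X, h, q, beta, lam, gamma, mix, fam, tol, max_sweeps):
    """Coordinate descent for 0.5*sum_i h_i (q_i - x_i.beta)^2 + sum_j P(beta_j).

    Full sweeps alternate with active-set sweeps; X should be Fortran order.
    Returns the number of sweeps used.
    """
    n, p = X.shape
    r = q - X @ beta
    c = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += h[i] * X[i, j] * X[i, j]
        c[j] = s
    sweeps = 0
    while sweeps < max_sweeps:
        # full sweep
        maxd = 0.0
        for j in range(p):
            if c[j] <= 0.0:
                continue
            s = 0.0
            for i in range(n):
                s += h[i] * X[i, j] * r[i]
            z = s / c[j] + beta[j]
            bnew = _threshold(z, c[j], lam, gamma, mix, fam)
            d = bnew - beta[j]
            if d != 0.0:
                for i in range(n):
                    r[i] -= X[i, j] * d
                beta[j] = bnew
                if abs(d) > maxd:
                    maxd = abs(d)
        sweeps += 1
        if maxd < tol:
            break
        # active-set sweeps over the current support
        active = np.flatnonzero(beta)
        while sweeps < max_sweeps:
            maxd_a = 0.0
            for jj in range(active.size):
                j = active[jj]
                if c[j] <= 0.0:
                    continue
                s = 0.0
                for i in range(n):
                    s += h[i] * X[i, j] * r[i]
                z = s / c[j] + beta[j]
                bnew = _threshold(z, c[j], lam, gamma, mix, fam)
                d = bnew - beta[j]
                if d != 0.0:
                    for i in range(n):
                        r[i] -= X[i, j] * d
                    beta[j] = bnew
                    if abs(d) > maxd_a:
                        maxd_a = abs(d)
            sweeps += 1
            if maxd_a < tol:
                break
    return sweeps


def _irls_cox(X, time, status, spec: PenaltySpec, beta0, max_iter, tol):
    """IRLS outer loop around penalized weighted least squares; returns (beta, iters, conv, nll)."""
    Xf = np.asfortranarray(X)
    beta = np.asarray(beta0, dtype=float).copy()
    lam, gamma, mix, fam = spec.lam, spec.gamma, spec.mix, spec.fam_code
    nll = np.inf
    for it in range(1, max_iter + 1):
        eta = X @ beta
        nll, g, h = _risk_set_terms(time, status, eta)
        h = np.maximum(h, _HESS_FLOOR)
        q = eta - g / h  # working response
        beta_old = beta.copy()
        _cd_solve(Xf, h, q, beta, lam, gamma, mix, fam, 0.1 * tol, 200)
        if np.max(np.abs(beta - beta_old)) < tol:
            nll, _, _ = _risk_set_terms(time, status, X @ beta)
            return beta, it, True, nll
    nll, _, _ = _risk_set_terms(time, status, X @ beta)
    return beta, max_iter, False, nll


def lambda_max(data: SurvivalDataset, spec: PenaltySpec) -> float:
    """Smallest lambda at which the penalized Cox solution is identically zero."""
    g0 = cox_gradient(np.zeros(data.p), data)
    lmax = float(np.max(np.abs(g0)))
    if spec.family == "elastic_net":
        lmax /= spec.mix
    return lmax


def _lambda_path(lmax: float, n_lambdas: int, min_ratio: float) -> np.ndarray:
    return np.exp(np.linspace(np.log(lmax), np.log(lmax * min_ratio), n_lambdas))


def _fit_cox_path(X, time, status, spec: PenaltySpec, lambdas, max_iter=6, tol=1e-3):
    """Warm-started fits down a descending lambda path; returns (n_lam, p) betas.

    Path fits use loose IRLS settings; warm starts keep successive solutions
    close enough that a handful of reweighting steps suffices for lambda
    selection and for seeding the final (tight) fit.
    """
    p = X.shape[1]
    betas = np.zeros((len(lambdas), p))
    beta = np.zeros(p)
    for k, lam in enumerate(lambdas):
        beta, _, _, _ = _irls_cox(X, time, status, spec.with_lam(lam), beta, max_iter, tol)
        betas[k] = beta
    return betas


def _stratified_folds(status, n_folds, rng):
    """Fold labels stratified by event status so every fold sees events."""
    n = len(status)
    folds = np.empty(n, dtype=int)
    for grp in (0, 1):
        idx = np.flatnonzero(np.asarray(status) == grp)
        idx = rng.permutation(idx)
        for k, i in enumerate(idx):
            folds[i] = k % n_folds
    return folds


def cv_cox_lambda(
    data: SurvivalDataset,
    spec: PenaltySpec,
    n_folds: int = 5,
    n_lambdas: int = 50,
    lambda_min_ratio: float = 0.01,
    seed: int = 0,
    max_iter: int = 3,
    tol: float = 1e-3,
) -> float:
    """Select lambda by K-fold cross-validated partial likelihood.

    Uses the Verweij-van-Houwelingen fold deviance
    ``nll_all(beta_k) - nll_train(beta_k)`` summed over folds; ties between
    lambdas resolve to the larger (sparser) value.
    """
    lambdas = _lambda_path(lambda_max(data, spec), n_lambdas, lambda_min_ratio)
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(data.status, n_folds, rng)
    cv_dev = np.zeros(len(lambdas))
    for k in range(n_folds):
        tr = np.flatnonzero(folds != k)
        Xtr, ttr, str_ = data.X[tr], data.time[tr], data.status[tr]
        if str_.sum() < 2:
            continue
        betas = _fit_cox_path(Xtr, ttr, str_, spec, lambdas, max_iter, tol)
        for i, b in enumerate(betas):
            nll_all, _, _ = _risk_set_terms(data.time, data.status, data.X @ b)
            nll_tr, _, _ = _risk_set_terms(ttr, str_, Xtr @ b)
            cv_dev[i] += nll_all - nll_tr
    return float(lambdas[int(np.argmin(cv_dev))])


def fit_penalized_cox(
    data: SurvivalDataset,
    spec: PenaltySpec,
    max_iter: int = 300,
    tol: float = 1e-6,
    cv_folds: int = 5,
    n_lambdas: int = 50,
    lambda_min_ratio: float = 0.01,
    seed: int = 0,
) -> CoxFit:
    """Fit the penalized Cox model; lambda is cross-validated when unset.

    Raises if the data contain no events; warns (and returns the fit with
    ``converged=False``) on non-convergence.
    """
    if data.n_events < 1:
        raise ValueError("cannot fit a Cox model with no events")
    spec_resolved = spec
    if spec.lam is None:
        if data.n_events < 2:
            raise ValueError("lambda cross-validation needs at least 2 events")
        lam = cv_cox_lambda(
            data, spec, n_folds=cv_folds, n_lambdas=n_lambdas,
            lambda_min_ratio=lambda_min_ratio, seed=seed,
        )
        spec_resolved = spec.with_lam(lam)
        # warm-start the final fit down the path for stability of the
        # non-convex (MCP) objective
        lambdas = _lambda_path(lambda_max(data, spec), n_lambdas, lambda_min_ratio)
        lambdas = lambdas[lambdas >= lam * (1 - 1e-12)]
        beta = np.zeros(data.p)
        for l in lambdas:
            beta, _, _, _ = _irls_cox(
                data.X, data.time, data.status, spec.with_lam(l), beta, 6, 1e-3
            )
        beta, n_it, conv, nll = _irls_cox(
            data.X, data.time, data.status, spec_resolved, beta, max_iter, tol
        )
    else:
        beta, n_it, conv, nll = _irls_cox(
            data.X, data.time, data.status, spec_resolved, np.zeros(data.p), max_iter, tol
        )
    if not conv:
        warnings.warn(
            f"penalized Cox did not converge in {max_iter} iterations", RuntimeWarning,
            stacklevel=2,
        )
    return CoxFit(
        beta=beta,
        support=np.flatnonzero(beta),
        lam_used=float(spec_resolved.lam),
        n_iterations=n_it,
        converged=conv,
        partial_loglik=-nll,
    )


def prognostic_index(fit: CoxFit, X: np.ndarray) -> np.ndarray:
    """Linear predictor x'beta per sample (higher = higher hazard)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != fit.beta.shape[0]:
        raise ValueError(f"X has {X.shape[1]} columns, beta has {fit.beta.shape[0]}")
    return X @ fit.beta


def classify_risk(pi, threshold: float | None = None) -> RiskGroups:
    """Median split of the prognostic index into high/low risk groups.

    ``threshold`` defaults to the median of ``pi`` (the training split rule);
    pass a stored training threshold to classify new samples.  Ties at the
    threshold go to "low".
    """
    pi = np.asarray(pi, dtype=float)
    if pi.size < 2 and threshold is None:
        raise ValueError("need at least 2 samples to form risk groups")
    if threshold is None:
        threshold = float(np.median(pi))
    if np.all(pi == pi[0]):
        warnings.warn(
            "constant prognostic index; assigning all samples to the low-risk group",
            RuntimeWarning,
            stacklevel=2,
        )
    labels = np.where(pi > threshold, "high", "low")
    return RiskGroups(labels=labels, threshold=float(threshold))


def km_estimator(time, status) -> KMCurve:
    """Kaplan-Meier product-limit estimator over the distinct event times."""
    time = np.asarray(time, dtype=float)
    status = np.asarray(status)
    if time.size < 1:
        raise ValueError("need at least one observation")
    ev_times = np.unique(time[status == 1])
    surv = np.empty(ev_times.size)
    s = 1.0
    for k, t in enumerate(ev_times):
        n_k = np.sum(time >= t)
        d_k = np.sum((time == t) & (status == 1))
        s *= 1.0 - d_k / n_k
        surv[k] = s
    return KMCurve(event_times=ev_times, survival_prob=surv)
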