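"""Outer semi-supervised loop: Cox risk stratification feeding group-specific
self-paced AFT pseudo-labeling, with confident censored samples promoted to
labeled status across rounds.

Also provides the no-SPL ablation (all censored samples kept each iteration,
constraint violators dismissed only at the end) and the plain supervised
penalized-Cox baselines.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .aft import AftFit, cv_aft_lambda, fit_penalized_aft
from .cox import CoxFit, RiskGroups, classify_risk, fit_penalized_cox, km_estimator, prognostic_index
from .data_model import SurvivalDataset
from .penalties import PenaltySpec
from .sp_aft import SPConfig, fit_sp_aft

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_cox_sp_aft",
    "run_semi_cox_baseline",
    "run_supervised_baseline",
]


@dataclass
class PipelineConfig:
    """All stage parameters of the semi-supervised loop."""

    cox_penalty: PenaltySpec = field(default_factory=lambda: PenaltySpec("mcp"))
    aft_penalty: PenaltySpec = field(default_factory=lambda: PenaltySpec("mcp"))
    sp: SPConfig = field(default_factory=SPConfig)
    max_outer_rounds: int = 5
    min_group_labeled: int = 10
    use_spl: bool = True
    seed: int = 0
    # lambda-selection controls (cross-validation)
    cox_cv_folds: int = 5
    cox_n_lambdas: int = 50
    cox_lambda_min_ratio: float = 0.01
    aft_cv_folds: int = 5
    aft_n_lambdas: int = 30

    def __post_init__(self) -> None:
        if self.max_outer_rounds < 1 or self.min_group_labeled < 1:
            raise ValueError("max_outer_rounds and min_group_labeled must be positive")


@dataclass
class PipelineResult:
    """Final Cox fit plus the augmented training set and per-round audit trail."""

    final_fit: CoxFit
    audit: list
    augmented: SurvivalDataset
    group_aft: dict
    risk: RiskGroups
    promoted: np.ndarray  # boolean mask over training samples
    pseudo_time: np.ndarray  # exported time per sample (original unless promoted)
    original_time: np.ndarray
    fallback_aft: AftFit | None = None

    @property
    def n_promoted(self) -> int:
        return int(self.promoted.sum())

    def predict_log_time(self, X: np.ndarray) -> np.ndarray:
        """Group-routed AFT log-time prediction for new samples.

        Samples are assigned to the high/low risk group by the final Cox
        prognostic index and the stored training threshold, then scored with
        that group's AFT fit (or the pooled fallback fit when a group's AFT
        was never trained).
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        pi = prognostic_index(self.final_fit, X)
        out = np.empty(X.shape[0])
        for g in ("low", "high"):
            mask = (pi > self.risk.threshold) == (g == "high")
            fit = self.group_aft.get(g) or self.fallback_aft
            if fit is None:
                raise RuntimeError("no AFT fit available for prediction")
            out[mask] = fit.predict_log_time(X[mask])
        return out


def _fit_cox(data: SurvivalDataset, spec: PenaltySpec, config: PipelineConfig) -> CoxFit:
    return fit_penalized_cox(
        data,
        spec,
        cv_folds=config.cox_cv_folds,
        n_lambdas=config.cox_n_lambdas,
        lambda_min_ratio=config.cox_lambda_min_ratio,
        seed=config.seed,
    )


def run_cox_sp_aft(train: SurvivalDataset, config: PipelineConfig) -> PipelineResult:
    """Run the full semi-supervised loop on a (standardized) training set.

    Per outer round: fit penalized Cox on the current labeled view, split all
    samples into high/low risk at the median prognostic index, run the
    (self-paced) AFT stage within each group, and promote censored samples
    that end with weight 1 and an imputed time strictly above their censoring
    time.  Stops at a promotion fixed point or after ``max_outer_rounds``.
    """
    if train.n_events < config.min_group_labeled:
        raise ValueError(
            f"need at least min_group_labeled={config.min_group_labeled} labeled samples, "
            f"got {train.n_events}"
        )
    n = train.n
    promoted = np.zeros(n, dtype=bool)
    pseudo_time = train.time.astype(float).copy()
    audit: list[dict] = []
    group_aft: dict[str, AftFit] = {}

    for rnd in range(1, config.max_outer_rounds + 1):
        cur_status = np.where(promoted, 1, train.status)
        cur_time = np.where(promoted, pseudo_time, train.time)
        cur = SurvivalDataset(
            X=train.X, time=cur_time, status=cur_status,
            sample_ids=list(train.sample_ids), gene_ids=list(train.gene_ids),
        )
        cox_fit = _fit_cox(cur, config.cox_penalty, config)
        pi = prognostic_index(cox_fit, train.X)
        risk = classify_risk(pi)
        new_promotions = 0
        round_info = {
            "round": rnd,
            "lam_cox": cox_fit.lam_used,
            "n_labeled": int(cur_status.sum()),
            "groups": {},
        }
        for g in ("low", "high"):
            gmask = risk.labels == g
            lab_idx = np.flatnonzero(gmask & (cur_status == 1))
            cen_idx = np.flatnonzero(gmask & (cur_status == 0))
            ginfo = {"n_labeled": int(lab_idx.size), "n_censored": int(cen_idx.size)}
            round_info["groups"][g] = ginfo
            if lab_idx.size < config.min_group_labeled:
                logger.info(
                    "round %d: skipping %s-risk group (%d labeled < %d)",
                    rnd, g, lab_idx.size, config.min_group_labeled,
                )
                ginfo["skipped"] = True
                continue
            labeled_ds = cur.subset(lab_idx)
            censored_ds = cur.subset(cen_idx)
            aft_spec = config.aft_penalty
            if aft_spec.lam is None:
                lam = cv_aft_lambda(
                    labeled_ds.X, np.log(labeled_ds.time), aft_spec,
                    n_folds=config.aft_cv_folds, n_lambdas=config.aft_n_lambdas,
                    seed=config.seed,
                )
                aft_spec = aft_spec.with_lam(lam)
            ginfo["lam_aft"] = aft_spec.lam
            fit, state = fit_sp_aft(
                labeled_ds, censored_ds, aft_spec, config.sp, use_spl=config.use_spl
            )
            group_aft[g] = fit
            # promote confident censored samples
            n_retained = 0
            for k, j in enumerate(cen_idx):
                if state.weights[k] != 1:
                    continue
                new_time = float(np.exp(state.pseudo_log_time[k]))
                if new_time <= train.time[j]:
                    continue  # promotion must strictly exceed the censoring time
                n_retained += 1
                if not promoted[j]:
                    new_promotions += 1
                promoted[j] = True
                pseudo_time[j] = new_time
            # refresh pseudo-times of previously promoted samples in this group
            prev_promoted = lab_idx[promoted[lab_idx]]
            if prev_promoted.size:
                refreshed = np.exp(fit.predict_log_time(train.X[prev_promoted]))
                ok = refreshed > train.time[prev_promoted]
                pseudo_time[prev_promoted[ok]] = refreshed[ok]
            ginfo["n_promoted"] = n_retained
            ginfo["sp_rounds"] = int(state.round)
        round_info["new_promotions"] = new_promotions
        audit.append(round_info)
        if new_promotions == 0:
            break

    # final Cox fit on the augmented labeled view
    aug = SurvivalDataset(
        X=train.X,
        time=np.where(promoted, pseudo_time, train.time),
        status=np.where(promoted, 1, train.status),
        sample_ids=list(train.sample_ids),
        gene_ids=list(train.gene_ids),
    )
    final_fit = _fit_cox(aug, config.cox_penalty, config)
    risk = classify_risk(prognostic_index(final_fit, train.X))
    fallback = None
    if any(g not in group_aft for g in ("low", "high")):
        lab = np.flatnonzero(aug.status == 1)
        aft_spec = config.aft_penalty
        if aft_spec.lam is None:
            aft_spec = aft_spec.with_lam(
                cv_aft_lambda(
                    aug.X[lab], np.log(aug.time[lab]), aft_spec,
                    n_folds=config.aft_cv_folds, n_lambdas=config.aft_n_lambdas,
                    seed=config.seed,
                )
            )
        fallback = fit_penalized_aft(aug.X[lab], np.log(aug.time[lab]), aft_spec)
    # promotion-safety invariant
    assert np.all(aug.time[promoted] > train.time[promoted]), "promotion safety violated"
    return PipelineResult(
        final_fit=final_fit,
        audit=audit,
        augmented=aug,
        group_aft=group_aft,
        risk=risk,
        promoted=promoted,
        pseudo_time=np.where(promoted, pseudo_time, train.time),
        original_time=train.time.copy(),
        fallback_aft=fallback,
    )


def run_semi_cox_baseline(train: SurvivalDataset, config: PipelineConfig) -> PipelineResult:
    """No-SPL ablation: the AFT stage keeps all censored samples every
    iteration and dismisses only terminal constraint violators."""
    cfg = PipelineConfig(
        cox_penalty=config.cox_penalty,
        aft_penalty=config.aft_penalty,
        sp=config.sp,
        max_outer_rounds=config.max_outer_rounds,
        min_group_labeled=config.min_group_labeled,
        use_spl=False,
        seed=config.seed,
        cox_cv_folds=config.cox_cv_folds,
        cox_n_lambdas=config.cox_n_lambdas,
        cox_lambda_min_ratio=config.cox_lambda_min_ratio,
        aft_cv_folds=config.aft_cv_folds,
        aft_n_lambdas=config.aft_n_lambdas,
    )
    return run_cox_sp_aft(train, cfg)


def run_supervised_baseline(
    train: SurvivalDataset, family: str, config: PipelineConfig | None = None
) -> CoxFit:
    """Plain penalized Cox on the training data (censored samples stay in the
    risk sets as ordinary censored observations)."""
    if config is None:
        config = PipelineConfig()
    spec = PenaltySpec(
        family,
        lam=config.cox_penalty.lam if config.cox_penalty.family == family else None,
        gamma=config.cox_penalty.gamma,
        mix=config.cox_penalty.mix,
    )
    return fit_penalized_cox(
        train,
        spec,
        cv_folds=config.cox_cv_folds,
        n_lambdas=config.cox_n_lambdas,
        lambda_min_ratio=config.cox_lambda_min_ratio,
        seed=config.seed,
    )
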