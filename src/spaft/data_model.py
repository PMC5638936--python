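"""Core survival-data container, validation, and delimited-text I/O.

Internally samples are always rows and genes are columns.  Expression files
are TSV/CSV with a header row of gene ids and a first column of sample ids;
survival files carry ``sample_id``, ``time``, ``status`` columns.  The
delimiter is auto-detected (tab vs comma) from the header line.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalDataset",
    "StandardizationRecord",
    "TrueModel",
    "read_dataset",
    "write_dataset",
    "standardize",
    "inverse_standardize",
    "split_train_test",
]


@dataclass
class SurvivalDataset:
    """Expression matrix plus per-sample observed time and event status.

    Attributes
    ----------
    X : (n, p) float array
        Expression values, samples as rows.
    time : (n,) float array
        Observed time, strictly positive.  For censored samples this is the
        censoring time (a lower bound on the true survival time).
    status : (n,) int array
        Event indicator: 1 = event observed (labeled), 0 = censored.
    sample_ids, gene_ids : lists of str
    """

    X: np.ndarray
    time: np.ndarray
    status: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.time = np.asarray(self.time, dtype=float).ravel()
        self.status = np.asarray(self.status).ravel()
        n, p = self.X.shape
        if not self.sample_ids:
            self.sample_ids = [f"S{i}" for i in range(n)]
        if not self.gene_ids:
            self.gene_ids = [f"G{j}" for j in range(p)]
        self.validate()

    def validate(self) -> None:
        n, p = self.X.shape
        if len(self.time) != n or len(self.status) != n:
            raise ValueError(f"time/status length must equal n={n}")
        if len(self.sample_ids) != n:
            raise ValueError(f"expected {n} sample ids, got {len(self.sample_ids)}")
        if len(self.gene_ids) != p:
            raise ValueError(f"expected {p} gene ids, got {len(self.gene_ids)}")
        if np.any(~np.isfinite(self.X)):
            raise ValueError("expression matrix contains missing or non-finite values")
        bad_t = np.where(~(self.time > 0) | ~np.isfinite(self.time))[0]
        if bad_t.size:
            raise ValueError(f"non-positive or non-finite time at row index {bad_t[0]}")
        vals = np.unique(np.asarray(self.status, dtype=float))
        if not np.all(np.isin(vals, (0.0, 1.0))):
            bad = np.where(~np.isin(np.asarray(self.status, dtype=float), (0.0, 1.0)))[0]
            raise ValueError(f"status must be 0/1; offending row index {bad[0]}")
        self.status = np.asarray(self.status, dtype=int)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    def subset(self, idx) -> "SurvivalDataset":
        """Row subset in the given index order."""
        idx = np.asarray(idx, dtype=int)
        return SurvivalDataset(
            X=self.X[idx],
            time=self.time[idx],
            status=self.status[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            gene_ids=list(self.gene_ids),
        )

    def copy(self) -> "SurvivalDataset":
        return SurvivalDataset(
            X=self.X.copy(),
            time=self.time.copy(),
            status=self.status.copy(),
            sample_ids=list(self.sample_ids),
            gene_ids=list(self.gene_ids),
        )


@dataclass
class StandardizationRecord:
    """Per-gene location/scale used to standardize a dataset (and undo it)."""

    mean: np.ndarray
    scale: np.ndarray
    kept: np.ndarray  # boolean mask over the original gene axis

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        self.kept = np.asarray(self.kept, dtype=bool)
        if np.any(self.scale <= 0):
            raise ValueError("standardization scale must be positive for every retained gene")


@dataclass
class TrueModel:
    """Simulation ground truth: true coefficients and uncensored times."""

    beta_true: np.ndarray
    true_support: np.ndarray
    true_times: np.ndarray

    def __post_init__(self) -> None:
        self.beta_true = np.asarray(self.beta_true, dtype=float)
        self.true_support = np.asarray(self.true_support, dtype=int)
        self.true_times = np.asarray(self.true_times, dtype=float)
        nz = np.flatnonzero(self.beta_true)
        if len(nz) != len(self.true_support) or not np.array_equal(
            np.sort(self.true_support), nz
        ):
            raise ValueError("true_support must index exactly the nonzero entries of beta_true")


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_dataset(expression_path, survival_path, genes_as_rows: bool = False) -> SurvivalDataset:
    """Read an expression table and a survival table into a SurvivalDataset.

    The survival file's row order governs the sample order of the result.
    """
    expression_path, survival_path = Path(expression_path), Path(survival_path)
    for p in (expression_path, survival_path):
        if not p.exists():
            raise FileNotFoundError(f"input file not found: {p}")
    expr = pd.read_csv(
        expression_path, sep=_sniff_delimiter(expression_path), index_col=0,
        float_precision="round_trip",
    )
    if genes_as_rows:
        expr = expr.T
    surv = pd.read_csv(
        survival_path, sep=_sniff_delimiter(survival_path), float_precision="round_trip"
    )
    required = {"sample_id", "time", "status"}
    if not required.issubset(surv.columns):
        raise ValueError(f"survival table must have columns {sorted(required)}; got {list(surv.columns)}")
    expr.index = expr.index.astype(str)
    surv_ids = surv["sample_id"].astype(str).tolist()
    missing = [s for s in surv_ids if s not in expr.index]
    if missing:
        raise ValueError(f"sample id {missing[0]!r} in survival table has no expression row")
    extra = [s for s in expr.index if s not in set(surv_ids)]
    if extra:
        raise ValueError(f"sample id {extra[0]!r} in expression table has no survival row")
    expr = expr.loc[surv_ids]
    status_raw = surv["status"].to_numpy()
    if not np.all(np.isin(np.asarray(status_raw, dtype=object), (0, 1, 0.0, 1.0))):
        bad = [i for i, v in enumerate(status_raw) if v not in (0, 1, 0.0, 1.0)]
        raise ValueError(f"status must be coded 0/1; offending survival row {bad[0]}")
    return SurvivalDataset(
        X=expr.to_numpy(dtype=float),
        time=surv["time"].to_numpy(dtype=float),
        status=np.asarray(status_raw, dtype=int),
        sample_ids=surv_ids,
        gene_ids=[str(g) for g in expr.columns],
    )


def write_dataset(data: SurvivalDataset, expression_path, survival_path, sep: str = "\t") -> None:
    """Write a dataset as an expression table + survival table (round-trip safe)."""
    expr = pd.DataFrame(data.X, index=data.sample_ids, columns=data.gene_ids)
    expr.index.name = "sample_id"
    # %.17g guarantees float64 round-trips bit-for-bit through text
    expr.to_csv(expression_path, sep=sep, float_format="%.17g")
    surv = pd.DataFrame(
        {"sample_id": data.sample_ids, "time": data.time, "status": data.status}
    )
    surv.to_csv(survival_path, sep=sep, index=False, float_format="%.17g")


def standardize(data: SurvivalDataset) -> tuple[SurvivalDataset, StandardizationRecord]:
    """Center each gene to mean 0 and scale to unit sample standard deviation.

    Genes with zero variance are dropped with a warning; an all-constant
    matrix is an error.
    """
    mean = data.X.mean(axis=0)
    sd = data.X.std(axis=0, ddof=1) if data.n > 1 else np.zeros(data.p)
    # relative floor: a numerically-constant column has sd ~ eps * |mean|
    kept = sd > 1e-12 * np.maximum(1.0, np.abs(mean))
    if not kept.any():
        raise ValueError("all genes have zero variance; nothing to standardize")
    if not kept.all():
        dropped = [data.gene_ids[j] for j in np.flatnonzero(~kept)]
        warnings.warn(
            f"dropping {len(dropped)} zero-variance gene(s): {dropped[:5]}",
            RuntimeWarning,
            stacklevel=2,
        )
        logger.warning("dropped %d zero-variance genes", len(dropped))
    Xs = (data.X[:, kept] - mean[kept]) / sd[kept]
    out = SurvivalDataset(
        X=Xs,
        time=data.time.copy(),
        status=data.status.copy(),
        sample_ids=list(data.sample_ids),
        gene_ids=[g for g, k in zip(data.gene_ids, kept) if k],
    )
    return out, StandardizationRecord(mean=mean[kept], scale=sd[kept], kept=kept)


def apply_standardization(data: SurvivalDataset, record: StandardizationRecord) -> SurvivalDataset:
    """Apply a fitted standardization (e.g. from the training split) to new data."""
    X = data.X[:, record.kept]
    return SurvivalDataset(
        X=(X - record.mean) / record.scale,
        time=data.time.copy(),
        status=data.status.copy(),
        sample_ids=list(data.sample_ids),
        gene_ids=[g for g, k in zip(data.gene_ids, record.kept) if k],
    )


def inverse_standardize(data: SurvivalDataset, record: StandardizationRecord) -> SurvivalDataset:
    """Undo :func:`standardize` on the retained genes."""
    X = data.X * record.scale + record.mean
    return SurvivalDataset(
        X=X,
        time=data.time.copy(),
        status=data.status.copy(),
        sample_ids=list(data.sample_ids),
        gene_ids=list(data.gene_ids),
    )


def split_train_test(
    data: SurvivalDataset, n_train: int, seed: int
) -> tuple[SurvivalDataset, SurvivalDataset]:
    """Deterministic disjoint+exhaustive random partition into train/test."""
    if not 0 < n_train < data.n:
        raise ValueError(f"n_train must be in (0, {data.n}), got {n_train}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(data.n)
    return data.subset(np.sort(perm[:n_train])), data.subset(np.sort(perm[n_train:]))
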