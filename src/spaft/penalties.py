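"""Sparsity penalties and their scalar proximal (thresholding) operators.

Three families are supported: the minimax concave penalty (MCP), the lasso,
and the elastic net.  The MCP value is

    P(b) = lam*|b| - b^2/(2*gamma)   if |b| <= gamma*lam
           gamma*lam^2/2             otherwise,

whose derivative is ``lam*sign(b)*max(0, 1 - |b|/(gamma*lam))``.  The
``threshold`` operator is the exact scalar minimizer of

    0.5*c*(b - z)^2 + P(b)

for step curvature ``c`` and is the only primitive the coordinate-descent
fitters need.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

FAMILIES = ("mcp", "lasso", "elastic_net")

# integer codes used by the jitted kernels
_FAM_MCP, _FAM_LASSO, _FAM_EN = 0, 1, 2
_FAM_CODE = {"mcp": _FAM_MCP, "lasso": _FAM_LASSO, "elastic_net": _FAM_EN}


@dataclass(frozen=True)
class PenaltySpec:
    """Penalty family with its tuning parameters.

    Parameters
    ----------
    family : {"mcp", "lasso", "elastic_net"}
    lam : float or None
        Tuning parameter ``lam >= 0``.  ``None`` means "to be selected by
        cross-validation" and is resolved by the fitters before use.
    gamma : float
        MCP concavity parameter (> 1); ignored by the other families.
    mix : float
        Elastic-net L1 mixing weight in (0, 1]; ignored by the other families.
    """

    family: str
    lam: float | None = None
    gamma: float = 3.0
    mix: float = 0.5

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown penalty family {self.family!r}; expected one of {FAMILIES}")
        if self.lam is not None and not (self.lam >= 0):
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        if self.family == "mcp" and not (self.gamma > 1):
            raise ValueError(f"gamma must be > 1 for mcp, got {self.gamma}")
        if self.family == "elastic_net" and not (0 < self.mix <= 1):
            raise ValueError(f"mix must be in (0, 1], got {self.mix}")

    def with_lam(self, lam: float) -> "PenaltySpec":
        return PenaltySpec(self.family, lam, self.gamma, self.mix)

    @property
    def fam_code(self) -> int:
        return _FAM_CODE[self.family]


@njit(cache=True)
def _penalty_value(b: float, lam: float, gamma: float, mix: float, fam: int) -> float:
    ab = abs(b)
    if fam == _FAM_MCP:
        if ab <= gamma * lam:
            return lam * ab - b * b / (2.0 * gamma)
        return 0.5 * gamma * lam * lam
    if fam == _FAM_LASSO:
        return lam * ab
    return lam * (mix * ab + 0.5 * (1.0 - mix) * b * b)


@njit(cache=True)
def _threshold(z: float, c: float, lam: float, gamma: float, mix: float, fam: int) -> float:
    """Exact minimizer of 0.5*c*(b - z)^2 + penalty(b) for step curvature c > 0."""
    if lam == 0.0:
        return z
    if fam == _FAM_LASSO:
        az = c * abs(z) - lam
        if az <= 0.0:
            return 0.0
        return np.sign(z) * az / c
    if fam == _FAM_EN:
        az = c * abs(z) - lam * mix
        if az <= 0.0:
            return 0.0
        return np.sign(z) * az / (c + lam * (1.0 - mix))
    # MCP: the objective is piecewise quadratic; evaluate the stationary points
    # of both branches plus the branch boundary and the origin, keep the best.
    best_b = 0.0
    best_f = 0.5 * c * z * z  # objective at b = 0
    s = 1.0 if z >= 0.0 else -1.0
    # inner branch stationary point (requires c*gamma != 1)
    denom = c - 1.0 / gamma
    if denom > 0.0:
        b1 = (c * abs(z) - lam) / denom
        if b1 > 0.0:
            if b1 > gamma * lam:
                b1 = gamma * lam
            bb = s * b1
            f = 0.5 * c * (bb - z) ** 2 + _penalty_value(bb, lam, gamma, mix, _FAM_MCP)
            if f < best_f:
                best_f = f
                best_b = bb
    else:
        # non-convex scalar problem: boundary of the inner branch
        bb = s * gamma * lam
        f = 0.5 * c * (bb - z) ** 2 + _penalty_value(bb, lam, gamma, mix, _FAM_MCP)
        if f < best_f:
            best_f = f
            best_b = bb
    # outer (flat-penalty) branch stationary point is b = z
    if abs(z) > gamma * lam:
        f = 0.5 * gamma * lam * lam  # 0.5*c*(z-z)^2 + const branch
        if f < best_f:
            best_f = f
            best_b = z
    return best_b


def penalty_value(beta_j, spec: PenaltySpec):
    """Penalty evaluated at a coefficient value (scalar or array)."""
    if spec.lam is None:
        raise ValueError("PenaltySpec.lam is unresolved (None)")
    b = np.asarray(beta_j, dtype=float)
    if b.ndim == 0:
        return float(_penalty_value(float(b), spec.lam, spec.gamma, spec.mix, spec.fam_code))
    ab = np.abs(b)
    if spec.family == "mcp":
        return np.where(
            ab <= spec.gamma * spec.lam,
            spec.lam * ab - b * b / (2.0 * spec.gamma),
            0.5 * spec.gamma * spec.lam**2,
        )
    if spec.family == "lasso":
        return spec.lam * ab
    return spec.lam * (spec.mix * ab + 0.5 * (1.0 - spec.mix) * b * b)


def penalty_derivative(beta_j, spec: PenaltySpec):
    """Derivative of the penalty (subgradient magnitude times sign away from 0)."""
    if spec.lam is None:
        raise ValueError("PenaltySpec.lam is unresolved (None)")
    b = np.asarray(beta_j, dtype=float)
    if spec.family == "mcp":
        return spec.lam * np.sign(b) * np.maximum(0.0, 1.0 - np.abs(b) / (spec.gamma * spec.lam))
    if spec.family == "lasso":
        return spec.lam * np.sign(b)
    return spec.lam * (spec.mix * np.sign(b) + (1.0 - spec.mix) * b)


def threshold(z: float, step_curvature: float, spec: PenaltySpec) -> float:
    """Minimizer of ``0.5*step_curvature*(b - z)**2 + penalty_value(b, spec)``.

    Soft-thresholding for the lasso, firm-thresholding for MCP, scaled
    soft-thresholding for the elastic net.  For MCP the scalar problem is only
    convex when ``step_curvature * gamma > 1``; if that fails we warn and fall
    back to the lasso rule.
    """
    if spec.lam is None:
        raise ValueError("PenaltySpec.lam is unresolved (None)")
    if not step_curvature > 0:
        raise ValueError("step_curvature must be positive")
    fam = spec.fam_code
    if fam == _FAM_MCP and step_curvature * spec.gamma <= 1.0:
        warnings.warn(
            "MCP curvature condition step_curvature*gamma > 1 violated; "
            "falling back to lasso thresholding",
            RuntimeWarning,
            stacklevel=2,
        )
        fam = _FAM_LASSO
    return float(_threshold(float(z), float(step_curvature), spec.lam, spec.gamma, spec.mix, fam))
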