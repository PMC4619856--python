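"""Finite-difference analysis operators, penalty family and shrinkage rules.

The penalty is the anisotropic analysis form

    Psi(Rx) = sum_i Phi(|[Rx]_i|)

over the 2N stacked horizontal/vertical first differences, with two
potentials:

* ``edge_preserving``: Phi(mu) = mu/s - log(1 + mu/s), s > 0 — smooth,
  edge-preserving (quadratic near 0, linear growth);
* ``l1``: Phi(mu) = mu — anisotropic total variation.

Both admit exact closed-form solutions (shrinkage rules) of the scalar
proximal subproblem  min_y Phi(|y|) + (gamma/2)(y - v)^2, which makes the
auxiliary update of the split formulation exact and separable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .geometry import ImageGrid

__all__ = [
    "RegularizerSpec",
    "DifferenceOperator",
    "build_difference_operator",
    "penalty_value",
    "smoothed_penalty_value",
    "smoothed_penalty_gradient",
    "penalty_curvature",
    "prox_l1",
    "prox_edge_preserving",
    "prox",
]

_KINDS = ("edge_preserving", "l1")


@dataclass(frozen=True)
class RegularizerSpec:
    """Penalty selection: kind, edge-preserving scale s, NCG smoothing eps."""

    kind: str
    s: float | None = None
    m1: int = 1
    smoothing_eps: float = 1e-6

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown regularizer kind {self.kind!r}; choose from {_KINDS}")
        if self.kind == "edge_preserving":
            if self.s is None or not self.s > 0:
                raise ValueError("edge_preserving regularizer requires scale s > 0")
        if self.m1 != 1:
            raise ValueError("only the m1 = 1 instances are implemented")
        if self.smoothing_eps < 0:
            raise ValueError("smoothing_eps must be non-negative")


@dataclass
class DifferenceOperator:
    """Stacked first-difference matrix R = [R1; R2], shape (2N, N).

    R1 takes horizontal forward differences, R2 vertical ones; rows at the
    far image boundary are identically zero (Neumann-like), so R annihilates
    constant images and keeps a fixed 2N x N shape.
    """

    R: sp.csr_matrix
    grid: ImageGrid
    P: int = 2

    @property
    def shape(self) -> tuple[int, int]:
        return self.R.shape

    def dot(self, x: np.ndarray) -> np.ndarray:
        return self.R @ x

    def rdot(self, v: np.ndarray) -> np.ndarray:
        return self.R.T @ v


def _diff_1d(n: int) -> sp.csr_matrix:
    """Forward-difference matrix with a zero last row, shape (n, n)."""
    d = sp.diags([-np.ones(n), np.ones(n - 1)], [0, 1], shape=(n, n), format="lil")
    d[n - 1, n - 1] = 0.0
    return d.tocsr()


def build_difference_operator(grid: ImageGrid) -> DifferenceOperator:
    if grid.nx < 2 or grid.ny < 2:
        raise ValueError("difference operator needs at least a 2x2 grid")
    R1 = sp.kron(sp.identity(grid.ny), _diff_1d(grid.nx), format="csr")
    R2 = sp.kron(_diff_1d(grid.ny), sp.identity(grid.nx), format="csr")
    R = sp.vstack([R1, R2], format="csr")
    R.eliminate_zeros()
    return DifferenceOperator(R=R, grid=grid)


def _phi_edge(mu: np.ndarray, s: float) -> np.ndarray:
    return mu / s - np.log1p(mu / s)


def penalty_value(Rx: np.ndarray, spec: RegularizerSpec) -> float:
    """Psi(Rx) = sum_i Phi(|[Rx]_i|) over the stacked difference components."""
    a = np.abs(np.asarray(Rx, dtype=float))
    if spec.kind == "l1":
        return float(a.sum())
    return float(_phi_edge(a, spec.s).sum())


def smoothed_penalty_value(Rx: np.ndarray, spec: RegularizerSpec) -> float:
    """Smooth surrogate used by gradient-based baselines.

    For l1 the nonsmooth |t| is replaced by sqrt(t^2 + eps^2) - eps; the
    edge-preserving potential is already smooth and used exactly.
    """
    t = np.asarray(Rx, dtype=float)
    if spec.kind == "l1":
        if spec.smoothing_eps <= 0:
            raise ValueError("l1 surrogate requires smoothing_eps > 0")
        e = spec.smoothing_eps
        return float(np.sum(np.sqrt(t * t + e * e) - e))
    return penalty_value(Rx, spec)


def smoothed_penalty_gradient(Rx: np.ndarray, spec: RegularizerSpec) -> np.ndarray:
    """Componentwise derivative of the (smoothed) potential at Rx."""
    t = np.asarray(Rx, dtype=float)
    if spec.kind == "l1":
        if spec.smoothing_eps <= 0:
            raise ValueError("l1 surrogate requires smoothing_eps > 0")
        e = spec.smoothing_eps
        return t / np.sqrt(t * t + e * e)
    # d/dt [ |t|/s - log(1+|t|/s) ] = t / (s (s + |t|))
    return t / (spec.s * (spec.s + np.abs(t)))


def penalty_curvature(Rx: np.ndarray, spec: RegularizerSpec) -> np.ndarray:
    """Componentwise second derivative of the (smoothed) potential at Rx."""
    t = np.asarray(Rx, dtype=float)
    if spec.kind == "l1":
        e = spec.smoothing_eps
        if e <= 0:
            raise ValueError("l1 surrogate requires smoothing_eps > 0")
        return e * e / (t * t + e * e) ** 1.5
    return 1.0 / (spec.s + np.abs(t)) ** 2


def prox_l1(v, gamma: float):
    """Soft threshold: exact minimizer of |y| + (gamma/2)(y - v)^2."""
    v = np.asarray(v, dtype=float)
    out = np.sign(v) * np.maximum(np.abs(v) - 1.0 / gamma, 0.0)
    return out if out.ndim else float(out)


def prox_edge_preserving(v, s: float, gamma: float):
    """Shrinkage rule: exact minimizer of Phi(|y|) + (gamma/2)(y - v)^2.

    y = sign(v) * (z + sqrt(z^2 + 4 s |v|)) / 2 with
    z = |v| - s - 1/(s*gamma); derived from the scalar stationarity
    condition y/(s(s+y)) + gamma (y - |v|) = 0 on y >= 0.
    """
    v = np.asarray(v, dtype=float)
    a = np.abs(v)
    z = a - s - 1.0 / (s * gamma)
    out = np.sign(v) * (z + np.sqrt(z * z + 4.0 * s * a)) / 2.0
    return out if out.ndim else float(out)


def prox(v, spec: RegularizerSpec, gamma: float):
    """Dispatch to the closed-form shrinkage for the configured potential."""
    if spec.kind == "l1":
        return prox_l1(v, gamma)
    return prox_edge_preserving(v, spec.s, gamma)
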