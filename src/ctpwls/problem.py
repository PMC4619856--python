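"""The PWLS objective, its augmented Lagrangian, and building blocks.

The reconstruction problem is

    x* = argmin_x  Psi(Rx) + (beta/2) (p - Hx)^T W^{-1} (p - Hx)

with H the system matrix, W = diag(sigma_i^2) the statistical weights, R
the stacked finite-difference operator and Psi the configured penalty.
Splitting y = Rx gives the augmented Lagrangian

    L(x, y, lam) = Psi(y) - lam^T (Rx - y) + (gamma/2) ||Rx - y||^2
                   + (beta/2) (p - Hx)^T W^{-1} (p - Hx)

whose x-gradient and separable exact y-update are provided here.  ``H`` and
``R`` may be any objects supporting ``@`` and ``.T`` (scipy sparse, dense
arrays), so small dense toy problems and full CT problems share one code
path.  W^{-1} is applied as elementwise division; no inverse is formed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .regularizers import RegularizerSpec, penalty_value, prox

__all__ = [
    "PWLSProblem",
    "LagrangianState",
    "pwls_objective",
    "augmented_lagrangian",
    "grad_x",
    "y_update",
    "select_gamma",
]

log = logging.getLogger(__name__)


@dataclass
class PWLSProblem:
    """Data, operators and hyper-parameters of one reconstruction problem."""

    H: object  # (M, N) linear operator supporting @ and .T
    w_diag: np.ndarray  # per-bin variance sigma_i^2 (length M)
    p: np.ndarray  # sinogram values (length M)
    R: object  # (L, N) analysis operator supporting @ and .T
    spec: RegularizerSpec
    beta: float
    gamma: float
    w_inv: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.beta > 0 or not self.gamma > 0:
            raise ValueError("beta and gamma must be positive")
        self.p = np.asarray(self.p, dtype=float).ravel()
        self.w_diag = np.asarray(self.w_diag, dtype=float).ravel()
        M, N = self.H.shape
        if self.p.size != M:
            raise ValueError(f"p has length {self.p.size}, H expects {M}")
        if self.w_diag.size != M:
            raise ValueError(f"w_diag has length {self.w_diag.size}, H expects {M}")
        if np.any(self.w_diag <= 0):
            raise ValueError("weight diagonal must be positive")
        if self.R.shape[1] != N:
            raise ValueError("R and H disagree on the image size")
        self.w_inv = 1.0 / self.w_diag

    @property
    def n_pixels(self) -> int:
        return self.H.shape[1]

    @property
    def n_aux(self) -> int:
        return self.R.shape[0]


@dataclass
class LagrangianState:
    """Iterate of the split problem: image x, auxiliary y, multiplier lam."""

    x: np.ndarray
    y: np.ndarray
    lam: np.ndarray

    def __post_init__(self) -> None:
        for name in ("x", "y", "lam"):
            v = np.asarray(getattr(self, name), dtype=float).ravel()
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, v)

    def constraint_residual(self, prob: PWLSProblem) -> float:
        """Relative splitting residual ||Rx - y|| / max(||Rx||, 1)."""
        Rx = prob.R @ self.x
        return float(np.linalg.norm(Rx - self.y) / max(np.linalg.norm(Rx), 1.0))


def _data_term(x: np.ndarray, prob: PWLSProblem) -> float:
    r = prob.p - prob.H @ x
    return 0.5 * prob.beta * float(r @ (prob.w_inv * r))


def pwls_objective(x: np.ndarray, prob: PWLSProblem) -> float:
    """Psi(Rx) + (beta/2)(p - Hx)^T W^{-1} (p - Hx)."""
    return penalty_value(prob.R @ x, prob.spec) + _data_term(x, prob)


def augmented_lagrangian(state: LagrangianState, prob: PWLSProblem) -> float:
    Rx = prob.R @ state.x
    c = Rx - state.y
    return (
        penalty_value(state.y, prob.spec)
        - float(state.lam @ c)
        + 0.5 * prob.gamma * float(c @ c)
        + _data_term(state.x, prob)
    )


def grad_x(state: LagrangianState, prob: PWLSProblem) -> np.ndarray:
    """Gradient of the augmented Lagrangian with respect to x:

    beta H^T W^{-1} (Hx - p) - R^T lam + gamma R^T (Rx - y).
    """
    r = prob.H @ state.x - prob.p
    g = prob.beta * (prob.H.T @ (prob.w_inv * r))
    g = g + prob.R.T @ (prob.gamma * (prob.R @ state.x - state.y) - state.lam)
    return np.asarray(g).ravel()


def y_update(x: np.ndarray, lam: np.ndarray, prob: PWLSProblem) -> np.ndarray:
    """Exact separable minimizer of L over y at fixed (x, lam).

    Componentwise y_i = prox(v_i) with v = Rx - lam/gamma; the prox is the
    closed-form shrinkage of the configured potential.
    """
    v = prob.R @ x - lam / prob.gamma
    return np.asarray(prox(v, prob.spec, prob.gamma), dtype=float)


def _power_lambda_max(apply_op, n: int, rng: np.random.Generator,
                      iters: int = 500, tol: float = 1e-4) -> tuple[float, np.ndarray]:
    """Largest eigenvalue of a symmetric PSD operator by power iteration."""
    v = rng.standard_normal(n)
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(iters):
        w = apply_op(v)
        nw = np.linalg.norm(w)
        if nw == 0:
            return 0.0, v
        lam_new = float(v @ w)
        v = w / nw
        if abs(lam_new - lam) <= tol * max(abs(lam_new), 1e-30):
            return lam_new, v
        lam = lam_new
    raise RuntimeError(
        f"power iteration did not converge in {iters} iterations "
        f"(last eigenvalue estimate {lam:.3e})"
    )


def select_gamma(prob: PWLSProblem, default: float = 1.0, seed: int = 0) -> float:
    """Advisory heuristic for the augmented penalty gamma.

    Balances the two blocks of the x-subproblem Hessian
    beta H^T W^{-1} H + gamma R^T R at the scale that minimizes its
    condition number, then applies the same factor-100 deflation as the
    empirical nu_min/100 rule.  Depends only on (H, W, R, beta), never on
    the sinogram content.  An explicit configured gamma always overrides.
    """
    rng = np.random.default_rng(seed)
    n = prob.n_pixels

    def apply_data(v):
        return prob.beta * (prob.H.T @ (prob.w_inv * (prob.H @ v)))

    def apply_reg(v):
        return prob.R.T @ (prob.R @ v)

    lam_h, _ = _power_lambda_max(apply_data, n, rng)
    lam_r, _ = _power_lambda_max(apply_reg, n, rng)

    # degenerate guard: both blocks act as scalars -> condition number is
    # gamma-independent, return the configured default
    u = rng.standard_normal(n)
    scalar_h = np.allclose(apply_data(u), lam_h * u, rtol=1e-8, atol=1e-12 * abs(lam_h))
    scalar_r = np.allclose(apply_reg(u), lam_r * u, rtol=1e-8, atol=1e-12 * abs(lam_r))
    if (scalar_h and scalar_r) or lam_r == 0 or lam_h == 0:
        log.info("select_gamma: degenerate spectrum, returning default %.3g", default)
        return default
    return lam_h / lam_r / 100.0
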