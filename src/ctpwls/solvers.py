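"""Iterative solvers for the PWLS reconstruction problem.

* ``anad_minimize`` — adaptive nonmonotone alternating direction (ANAD)
  inner solver: a Barzilai–Borwein-scaled gradient step in x accepted
  against a lagged reference value, alternated with the exact separable
  proximal update in y.
* ``alm_anad_reconstruct`` — the augmented-Lagrangian outer loop around
  ANAD with multiplier updates (ALM-ANAD).
* ``ncg_reconstruct`` — Polak–Ribière nonlinear conjugate gradient on the
  (smoothed) PWLS objective; the classical monotone baseline.
* ``sb_ncg_reconstruct`` — split-Bregman iteration whose quadratic
  x-subproblem is solved by a few inner NCG steps (SB-NCG).

All solvers emit a shared ``SolverTrace`` so convergence curves
(objective, gradient norm, constraint residual, SNR vs ground truth) are
directly comparable across methods.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .metrics import snr_db
from .problem import (
    LagrangianState,
    PWLSProblem,
    augmented_lagrangian,
    grad_x,
    pwls_objective,
    y_update,
)
from .regularizers import (
    penalty_curvature,
    prox,
    smoothed_penalty_gradient,
    smoothed_penalty_value,
)

__all__ = [
    "ANADParams",
    "ALMParams",
    "NCGParams",
    "SBParams",
    "LineSearchState",
    "BBHistory",
    "SolverTrace",
    "bb_step",
    "nonmonotone_line_search",
    "update_reference",
    "anad_minimize",
    "alm_anad_reconstruct",
    "ncg_reconstruct",
    "sb_ncg_reconstruct",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class ANADParams:
    """Inner-solver controls.

    Defaults follow the published settings: sufficient-decrease delta=1e-4,
    backtracking factor rho=0.5, BB safeguards rho_min=1/rho_max=1e-10,
    reference lag K=5, BB2 window h=3, gradient tolerance tol=1e-3.  The
    BB switching threshold tau is not published; 0.2 is a typical value for
    this family of rules.
    """

    delta: float = 1e-4
    rho: float = 0.5
    rho_min: float = 1e-10
    rho_max: float = 1e10
    tau: float = 0.2
    h: int = 3
    K: int = 5
    tol: float = 1e-3
    max_inner_iter: int = 10
    max_backtracks: int = 60

    def __post_init__(self) -> None:
        if not (0 < self.rho_min <= self.rho_max):
            raise ValueError("require 0 < rho_min <= rho_max")
        for name in ("delta", "rho", "tau"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.h < 1 or self.K < 1 or self.max_inner_iter < 1:
            raise ValueError("h, K and max_inner_iter must be positive integers")


@dataclass
class ALMParams:
    """Outer-loop controls: stop on relative x-change or iteration cap."""

    outer_tol: float = 1e-4
    max_outer: int = 100


@dataclass
class NCGParams:
    max_iter: int = 50
    tol: float = 1e-3
    delta: float = 1e-4
    rho: float = 0.5
    max_backtracks: int = 60


@dataclass
class SBParams:
    max_outer: int = 50
    inner_ncg_iters: int = 5
    outer_tol: float = 1e-4


# ---------------------------------------------------------------------------
# trace


@dataclass
class SolverTrace:
    """Per-iteration diagnostics shared by all solvers."""

    records: list = field(default_factory=list)

    def append(self, **kw) -> None:
        self.records.append(kw)

    def __len__(self) -> int:
        return len(self.records)

    def column(self, key: str) -> np.ndarray:
        return np.array([r.get(key, np.nan) for r in self.records], dtype=float)

    def to_csv(self, path) -> None:
        if not self.records:
            raise ValueError("empty trace")
        keys: list = []
        for r in self.records:
            for k in r:
                if k not in keys:
                    keys.append(k)
        with open(path, "w", newline="") as f:
            w = csv.DictWriter(f, fieldnames=keys)
            w.writeheader()
            w.writerows(self.records)


# ---------------------------------------------------------------------------
# ANAD building blocks


@dataclass
class LineSearchState:
    """Reference machinery of the adaptive nonmonotone line search."""

    phi_r: float
    phi_best: float
    phi_c: float
    l: int = 0


def update_reference(ls: LineSearchState, new_value: float, params: ANADParams) -> LineSearchState:
    """Reference-value update after a step produced objective ``new_value``.

    Improvement over phi_best resets the best/candidate values and the
    counter; otherwise the candidate tracks the worst recent value, and
    after K consecutive non-improvements the reference drops to it.
    """
    if new_value <= ls.phi_best:
        ls.phi_best = new_value
        ls.phi_c = new_value
        ls.l = 0
    else:
        ls.phi_c = max(ls.phi_c, new_value)
        ls.l += 1
        if ls.l == params.K:
            ls.phi_r = ls.phi_c
            ls.phi_c = new_value
            ls.l = 0
    return ls


@dataclass
class BBHistory:
    """Successive differences feeding the Barzilai–Borwein step.

    ``t_next`` caches the step computed from the most recent pair so a
    warm-started solver call does not re-consume the same differences.
    """

    s_prev: np.ndarray
    y_prev: np.ndarray
    recent_bb2: list = field(default_factory=list)
    t_next: float | None = None


def bb_step(hist: BBHistory, params: ANADParams) -> float:
    """Adaptive BB step: BB1 when s and y are well aligned, else the
    minimum of the recent BB2 values; always clamped to [rho_min, rho_max].
    """
    s, y = hist.s_prev, hist.y_prev
    ss = float(s @ s)
    yy = float(y @ y)
    if ss == 0.0 or yy == 0.0:
        raise ValueError("BB step undefined for zero difference vectors")
    sy = float(s @ y)
    if sy <= 0.0:
        log.debug("bb_step: non-positive curvature s'y=%.3e, falling back", sy)
        return float(np.clip(1.0, params.rho_min, params.rho_max))
    bb2 = sy / yy
    hist.recent_bb2.append(bb2)
    del hist.recent_bb2[: -params.h]
    cosine = sy / math.sqrt(ss * yy)
    t = ss / sy if cosine > params.tau else min(hist.recent_bb2)
    return float(np.clip(t, params.rho_min, params.rho_max))


def nonmonotone_line_search(
    x: np.ndarray,
    d: np.ndarray,
    y_fixed: np.ndarray,
    lam: np.ndarray,
    ls_state: LineSearchState,
    prob: PWLSProblem,
    params: ANADParams,
    g: np.ndarray | None = None,
):
    """Backtracking against the reference value phi_r.

    Finds the largest alpha in {rho^i} with
    phi(x + alpha d, y) <= phi_r + alpha * delta * grad'd and returns
    (alpha, x_new, phi_new).  d must be a descent-scaled direction
    d = -t * grad_1 phi; ``g`` may pass the already-computed gradient.
    """
    if g is None:
        g = grad_x(LagrangianState(x=x, y=y_fixed, lam=lam), prob)
    slope = float(g @ d)
    alpha = 1.0
    for _ in range(params.max_backtracks + 1):
        x_new = x + alpha * d
        phi_new = augmented_lagrangian(LagrangianState(x=x_new, y=y_fixed, lam=lam), prob)
        if phi_new <= ls_state.phi_r + alpha * params.delta * slope:
            return alpha, x_new, phi_new
        alpha *= params.rho
    raise RuntimeError(
        f"nonmonotone line search failed after {params.max_backtracks} backtracks "
        "(direction not usable)"
    )


# ---------------------------------------------------------------------------
# ANAD inner solver


def anad_minimize(
    prob: PWLSProblem,
    lam_fixed: np.ndarray,
    x0: np.ndarray,
    y0: np.ndarray,
    params: ANADParams,
    hist: BBHistory | None = None,
    ls_state: LineSearchState | None = None,
):
    """Minimize the augmented Lagrangian at fixed multiplier.

    Alternates a BB-scaled nonmonotone gradient step in x with the exact
    separable proximal update in y.  The iterate invariant y_k = y(x_k) is
    established on entry (gradients are always taken at the exact
    y-minimizer, which is what makes the x-gradient a subgradient
    surrogate for the reduced objective), so the passed ``y0`` only seeds
    degenerate cases where the y-subproblem is absent.  Terminates when
    the x-gradient norm falls below ``params.tol`` or after
    ``params.max_inner_iter`` iterations.  ``hist``/``ls_state`` allow the
    outer loop to warm-start the BB memory and reference machinery.

    Returns (x, y, trace, hist, ls_state).
    """
    x = np.asarray(x0, dtype=float).ravel().copy()
    lam = np.asarray(lam_fixed, dtype=float).ravel()
    y = y_update(x, lam, prob) if prob.n_aux else np.asarray(y0, dtype=float).ravel().copy()
    trace = SolverTrace()

    phi0 = augmented_lagrangian(LagrangianState(x=x, y=y, lam=lam), prob)
    if not np.isfinite(phi0):
        raise FloatingPointError("augmented Lagrangian is non-finite at the start point")
    if ls_state is None:
        ls_state = LineSearchState(phi_r=np.inf, phi_best=phi0, phi_c=phi0, l=0)

    g = grad_x(LagrangianState(x=x, y=y, lam=lam), prob)
    t = hist.t_next if hist is not None else None
    for _k in range(params.max_inner_iter):
        gnorm = float(np.linalg.norm(g))
        if gnorm <= params.tol:
            break
        if t is None:
            # first step: exact Cauchy step of the quadratic-in-x Lagrangian
            # (Psi(y) does not depend on x), safeguarded by the line search
            Hg = prob.H @ g
            Rg = prob.R @ g
            curv = prob.beta * float(Hg @ (prob.w_inv * Hg)) + prob.gamma * float(Rg @ Rg)
            t = gnorm * gnorm / curv if curv > 0 else 1.0 / max(gnorm, 1e-30)
            t = float(np.clip(t, params.rho_min, params.rho_max))
        d = -t * g
        alpha, x_new, phi_new = nonmonotone_line_search(
            x, d, y, lam, ls_state, prob, params, g=g
        )
        if not np.isfinite(phi_new):
            raise FloatingPointError("objective became non-finite during ANAD")
        update_reference(ls_state, phi_new, params)

        y_new = y_update(x_new, lam, prob)
        g_new = grad_x(LagrangianState(x=x_new, y=y_new, lam=lam), prob)
        # grad_1 phi(x, y_new) differs from grad_1 phi(x, y) only through
        # the splitting term: add gamma R^T (y - y_new)
        g_old_shift = g + prob.R.T @ (prob.gamma * (y - y_new))
        s_vec = x_new - x
        y_vec = g_new - g_old_shift
        if hist is None:
            hist = BBHistory(s_prev=s_vec, y_prev=y_vec)
        else:
            hist.s_prev, hist.y_prev = s_vec, y_vec
        try:
            t = bb_step(hist, params)
        except ValueError:
            t = None
        hist.t_next = t

        x, y, g = x_new, y_new, g_new
        trace.append(
            objective=phi_new,
            grad_norm=float(np.linalg.norm(g)),
            step=alpha * t if t is not None else alpha,
            alpha=alpha,
            phi_best=ls_state.phi_best,
        )
    return x, y, trace, hist, ls_state


# ---------------------------------------------------------------------------
# ALM outer loop


def alm_anad_reconstruct(
    prob: PWLSProblem,
    x0: np.ndarray,
    alm_params: ALMParams | None = None,
    anad_params: ANADParams | None = None,
    x_true: np.ndarray | None = None,
):
    """Full ALM-ANAD reconstruction.

    Starts from x0 (typically the FBP image), y0 = R x0, lam0 = 0; each
    outer iteration calls ANAD warm-started from the previous iterate, then
    updates the multiplier lam <- lam - gamma (Rx - y).  Stops when the
    relative change of x drops below the outer tolerance or the iteration
    cap is reached.  Returns (x, trace).
    """
    alm_params = alm_params or ALMParams()
    anad_params = anad_params or ANADParams()
    x = np.asarray(x0, dtype=float).ravel().copy()
    y = np.asarray(prob.R @ x).ravel()
    lam = np.zeros(prob.n_aux)
    trace = SolverTrace()
    hist: BBHistory | None = None
    ls_state: LineSearchState | None = None
    recent_obj: list = []

    for k in range(alm_params.max_outer):
        x_new, y_new, _inner, hist, ls_state = anad_minimize(
            prob, lam, x, y, anad_params, hist=hist, ls_state=ls_state
        )
        Rx = np.asarray(prob.R @ x_new).ravel()
        lam = lam - prob.gamma * (Rx - y_new)
        # the multiplier changed: the stored reference values no longer
        # describe the new augmented Lagrangian, so reset the machinery
        ls_state = None

        obj = pwls_objective(x_new, prob)
        residual = float(np.linalg.norm(Rx - y_new) / max(np.linalg.norm(Rx), 1.0))
        rel_change = float(np.linalg.norm(x_new - x) / max(np.linalg.norm(x), 1.0))
        rec = dict(
            outer_iter=k + 1,
            objective=obj,
            residual=residual,
            rel_change=rel_change,
            grad_norm=float(
                np.linalg.norm(grad_x(LagrangianState(x=x_new, y=y_new, lam=lam), prob))
            ),
        )
        if x_true is not None:
            rec["snr_db"] = snr_db(x_new, x_true)
        trace.append(**rec)

        recent_obj.append(obj)
        del recent_obj[:-5]
        if len(recent_obj) == 5 and obj > 10.0 * min(recent_obj):
            raise RuntimeError(
                "ALM-ANAD diverging: objective grew more than 10x over 5 outer iterations"
            )
        x, y = x_new, y_new
        if rel_change < alm_params.outer_tol:
            break
    return x, trace


# ---------------------------------------------------------------------------
# NCG baseline


def _smoothed_objective(x: np.ndarray, prob: PWLSProblem) -> float:
    r = prob.p - prob.H @ x
    return smoothed_penalty_value(prob.R @ x, prob.spec) + 0.5 * prob.beta * float(
        r @ (prob.w_inv * r)
    )


def _smoothed_gradient(x: np.ndarray, prob: PWLSProblem) -> np.ndarray:
    r = prob.H @ x - prob.p
    g = prob.beta * (prob.H.T @ (prob.w_inv * r))
    return np.asarray(g + prob.R.T @ smoothed_penalty_gradient(prob.R @ x, prob.spec)).ravel()


def _curvature_along(x: np.ndarray, d: np.ndarray, prob: PWLSProblem) -> float:
    """d' Hess d with the exact data curvature and the penalty's pointwise
    second derivative at the current Rx (local quadratic model)."""
    Hd = prob.H @ d
    Rd = prob.R @ d
    c = penalty_curvature(prob.R @ x, prob.spec)
    return prob.beta * float(Hd @ (prob.w_inv * Hd)) + float(Rd @ (c * Rd))


def ncg_reconstruct(
    prob: PWLSProblem,
    x0: np.ndarray,
    params: NCGParams | None = None,
    x_true: np.ndarray | None = None,
):
    """Polak–Ribière NCG on the (smoothed) PWLS objective.

    The initial trial step minimizes the local quadratic model along the
    search direction; an Armijo backtracking safeguard then enforces a
    monotone objective decrease.  Non-descent directions trigger a restart
    with steepest descent.  Returns (x, trace).
    """
    params = params or NCGParams()
    x = np.asarray(x0, dtype=float).ravel().copy()
    trace = SolverTrace()
    g = _smoothed_gradient(x, prob)
    d = -g
    f = _smoothed_objective(x, prob)
    for k in range(params.max_iter):
        gnorm = float(np.linalg.norm(g))
        if gnorm <= params.tol:
            break
        slope = float(g @ d)
        if slope >= 0:
            log.debug("ncg: non-descent direction at iter %d, restarting", k)
            d = -g
            slope = float(g @ d)
        curv = _curvature_along(x, d, prob)
        alpha = -slope / curv if curv > 0 else 1.0
        accepted = False
        for _ in range(params.max_backtracks + 1):
            x_new = x + alpha * d
            f_new = _smoothed_objective(x_new, prob)
            if f_new <= f + params.delta * alpha * slope:
                accepted = True
                break
            alpha *= params.rho
        if not accepted:
            raise RuntimeError("NCG line search failed (direction not usable)")
        g_new = _smoothed_gradient(x_new, prob)
        beta_pr = float(g_new @ (g_new - g)) / float(g @ g)
        d = -g_new + beta_pr * d
        x, g, f = x_new, g_new, f_new
        rec = dict(iter=k + 1, objective=f, grad_norm=float(np.linalg.norm(g)), step=alpha)
        if x_true is not None:
            rec["snr_db"] = snr_db(x, x_true)
        trace.append(**rec)
    return x, trace


# ---------------------------------------------------------------------------
# split-Bregman baseline


def sb_ncg_reconstruct(
    prob: PWLSProblem,
    x0: np.ndarray,
    params: SBParams | None = None,
    x_true: np.ndarray | None = None,
):
    """Split-Bregman iteration with an inner NCG x-solve (SB-NCG).

    Alternates (i) a few NCG steps on the smooth quadratic-coupled
    x-subproblem, (ii) the exact shrinkage y-update with v = Rx + b, and
    (iii) the additive Bregman update b <- b + (Rx - y).  Returns (x, trace).
    """
    params = params or SBParams()
    x = np.asarray(x0, dtype=float).ravel().copy()
    Rx = np.asarray(prob.R @ x).ravel()
    y = Rx.copy()
    b = np.zeros(prob.n_aux)
    trace = SolverTrace()

    def quad_grad(xv, target):
        r = prob.H @ xv - prob.p
        g = prob.beta * (prob.H.T @ (prob.w_inv * r))
        return np.asarray(g + prob.gamma * (prob.R.T @ (prob.R @ xv - target))).ravel()

    def quad_curv(dv):
        Hd = prob.H @ dv
        Rd = prob.R @ dv
        return prob.beta * float(Hd @ (prob.w_inv * Hd)) + prob.gamma * float(Rd @ Rd)

    for k in range(params.max_outer):
        target = y - b
        # inner NCG (exact steps on a quadratic = conjugate gradient)
        g = quad_grad(x, target)
        d = -g
        x_prev_outer = x
        for _ in range(params.inner_ncg_iters):
            gn2 = float(g @ g)
            if gn2 == 0.0:
                break
            curv = quad_curv(d)
            if curv <= 0:
                break
            alpha = -float(g @ d) / curv
            x = x + alpha * d
            g_new = quad_grad(x, target)
            beta_pr = float(g_new @ (g_new - g)) / gn2
            d = -g_new + beta_pr * d
            if float(g_new @ d) >= 0:
                d = -g_new
            g = g_new
        Rx = np.asarray(prob.R @ x).ravel()
        y = np.asarray(prox(Rx + b, prob.spec, prob.gamma), dtype=float)
        b = b + (Rx - y)

        obj = pwls_objective(x, prob)
        residual = float(np.linalg.norm(Rx - y) / max(np.linalg.norm(Rx), 1.0))
        rel_change = float(
            np.linalg.norm(x - x_prev_outer) / max(np.linalg.norm(x_prev_outer), 1.0)
        )
        rec = dict(outer_iter=k + 1, objective=obj, residual=residual, rel_change=rel_change)
        if x_true is not None:
            rec["snr_db"] = snr_db(x, x_true)
        trace.append(**rec)
        if rel_change < params.outer_tol:
            break
    return x, trace
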