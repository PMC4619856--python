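"""Low-dose transmission noise model and statistical weights.

The pre-log transmission counts follow a compound Poisson + Gaussian model

    I = Poisson(I0 * exp(-yhat)) + Normal(0, sigma_e^2),

where ``I0`` is the incident photon intensity per bin and ``sigma_e^2`` the
electronic noise variance.  After the log transform p = ln(I0 / I), the
per-bin variance of p is well approximated by the analytical formula

    sigma_i^2 = (1/I0) exp(p_i) * (1 + (1/I0) exp(p_i) * (sigma_e^2 - 1.25)),

which supplies the diagonal of the statistical weight matrix W used by the
penalized weighted least-squares objective.  The mean sinogram value at a
bin is not observable from a single noisy realization, so the measured
``p_i`` is plugged in by default; a smoothed estimate can be passed instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "NoiseParams",
    "WeightMatrix",
    "simulate_transmission",
    "log_transform",
    "estimate_variance",
]

#: counts below this are clamped before the log (photon-starved bins)
EPS_COUNT = 1.0
#: variance floor keeping W invertible
SIGMA2_FLOOR = 1e-12


@dataclass(frozen=True)
class NoiseParams:
    """Incident intensity I0 (photons/bin), electronic variance, RNG seed."""

    I0: float
    sigma_e2: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.I0 > 0:
            raise ValueError("I0 must be positive")
        if self.sigma_e2 < 0:
            raise ValueError("sigma_e2 must be non-negative")


@dataclass
class WeightMatrix:
    """Diagonal of W: per-bin variance sigma_i^2 of the log-transformed data."""

    diag: np.ndarray

    def __post_init__(self) -> None:
        self.diag = np.asarray(self.diag, dtype=float).ravel()
        if not np.all(np.isfinite(self.diag)) or np.any(self.diag <= 0):
            raise ValueError("weight diagonal must be positive and finite")

    @property
    def inv_diag(self) -> np.ndarray:
        return 1.0 / self.diag


def simulate_transmission(noise_free_sino: np.ndarray, params: NoiseParams) -> np.ndarray:
    """Draw noisy transmission counts for each ray of a noise-free sinogram.

    Input is the ideal line-integral array (any shape); output is a flat
    counts vector in row-major ray order.  Deterministic given the seed;
    draws are made over the row-major flattened array so the result is
    independent of the input's 2D layout.
    """
    yhat = np.asarray(noise_free_sino, dtype=float).ravel()
    if np.any(yhat < 0):
        raise ValueError("noise-free line integrals must be non-negative")
    rng = np.random.default_rng(params.seed)
    counts = rng.poisson(params.I0 * np.exp(-yhat)).astype(float)
    if params.sigma_e2 > 0:
        counts += rng.normal(0.0, np.sqrt(params.sigma_e2), size=yhat.size)
    return counts


def log_transform(I: np.ndarray, I0: float) -> np.ndarray:
    """p_i = ln(I0 / I_i), with sub-threshold counts clamped to EPS_COUNT."""
    I = np.asarray(I, dtype=float)
    return np.log(I0) - np.log(np.maximum(I, EPS_COUNT))


def estimate_variance(
    p: np.ndarray,
    params: NoiseParams,
    p_mean: np.ndarray | None = None,
) -> WeightMatrix:
    """Per-bin variance of the log sinogram from the analytical formula.

    ``p_mean`` is the mean sinogram estimate; defaults to the measured ``p``
    (plug-in).  Values are floored at a small positive epsilon, which can
    only engage when sigma_e2 < 1.25 at extreme bins.
    """
    pm = np.asarray(p if p_mean is None else p_mean, dtype=float).ravel()
    if not np.all(np.isfinite(pm)):
        raise ValueError("sinogram must be finite")
    e = np.exp(pm) / params.I0
    sigma2 = e * (1.0 + e * (params.sigma_e2 - 1.25))
    n_floored = int(np.count_nonzero(sigma2 < SIGMA2_FLOOR))
    if n_floored:
        log.warning("floored %d non-positive variance estimates", n_floored)
    return WeightMatrix(np.maximum(sigma2, SIGMA2_FLOOR))
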