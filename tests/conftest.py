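import numpy as np
import pytest
import scipy.sparse as sp

from ctpwls import (
    FanBeamGeometry,
    ImageGrid,
    PWLSProblem,
    RegularizerSpec,
    build_difference_operator,
    build_system_matrix,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def grid32():
    return ImageGrid(nx=32, ny=32, pixel_size_mm=1.0)


@pytest.fixture(scope="session")
def geom32():
    # detector sized to cover the 32 mm grid diagonal at the isocenter
    return FanBeamGeometry(
        n_views=16,
        n_bins=32,
        source_to_iso_mm=570.0,
        source_to_detector_mm=1040.0,
        bin_spacing_mm=1.407 * 2.0,
    )


@pytest.fixture(scope="session")
def sysmat32(grid32, geom32):
    return build_system_matrix(grid32, geom32)


def diff_1d_operator(n: int) -> sp.csr_matrix:
    """Forward-difference matrix for a 1D signal, zero last row."""
    d = sp.diags([-np.ones(n), np.ones(n - 1)], [0, 1], shape=(n, n), format="lil")
    d[n - 1, n - 1] = 0.0
    return d.tocsr()


def make_tv1d_problem(n=32, beta=2.0, gamma=5.0, noise=0.3, seed=3):
    """1D total-variation denoising: H = W = identity, R = first difference."""
    rng = np.random.default_rng(seed)
    signal = np.concatenate([np.full(n // 3, 1.0), np.full(n - 2 * (n // 3), 3.0), np.full(n // 3, 0.5)])
    data = signal + noise * rng.standard_normal(n)
    prob = PWLSProblem(
        H=sp.identity(n, format="csr"),
        w_diag=np.ones(n),
        p=data,
        R=diff_1d_operator(n),
        spec=RegularizerSpec(kind="l1"),
        beta=beta,
        gamma=gamma,
    )
    return prob, data


def make_dense_problem(grid_n=8, m=40, kind="edge_preserving", s=0.1, beta=3.0, gamma=2.0, seed=0):
    """Small dense random PWLS problem on a grid_n x grid_n image."""
    rng = np.random.default_rng(seed)
    grid = ImageGrid(nx=grid_n, ny=grid_n, pixel_size_mm=1.0)
    n = grid.n_pixels
    H = np.abs(rng.standard_normal((m, n)))
    w = rng.uniform(0.5, 2.0, m)
    p = H @ rng.standard_normal(n) + 0.1 * rng.standard_normal(m)
    R = build_difference_operator(grid).R
    spec = RegularizerSpec(kind=kind, s=s if kind == "edge_preserving" else None)
    return PWLSProblem(H=H, w_diag=w, p=p, R=R, spec=spec, beta=beta, gamma=gamma)


def tv1d_reference_solution(prob, iters=100_000):
    """Independent high-accuracy reference for 1D TV denoising.

    Solves min_x (beta/2)||x - p||^2 + ||Rx||_1 by projected gradient
    ascent on the box-constrained dual (x = p - R^T u / beta, |u| <= 1).
    Shares no code with the solvers under test.
    """
    R = prob.R
    p, beta = prob.p, prob.beta
    RRt = (R @ R.T).toarray()
    L = np.linalg.eigvalsh(RRt).max()
    t = beta / L
    u = np.zeros(R.shape[0])
    Rp = R @ p
    for _ in range(iters):
        u = np.clip(u + t * (Rp - RRt @ u / beta), -1.0, 1.0)
    return p - R.T @ u / beta
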