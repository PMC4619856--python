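"""Sparse fan-beam system matrix via exact Siddon-style ray traversal.

The system matrix ``H`` has one row per ray (view-major order) and one
column per pixel (row-major image order); the entry ``h_ij`` is the exact
length (mm) of the intersection of ray ``i`` with pixel ``j``.  Rays are
traced with an incremental grid-traversal (Amanatides–Woo / Siddon) so the
entries are exact up to floating-point rounding, and the adjoint pair
``H``/``Hᵀ`` is exact by construction (shared sparse storage).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from numba import njit

from .geometry import FanBeamGeometry, ImageGrid

__all__ = [
    "SystemMatrix",
    "build_system_matrix",
    "forward_project",
    "back_project",
    "save_system_matrix",
    "load_system_matrix",
]

_CACHE_VERSION = "ctpwls-sysmat-v1"


@njit(cache=False)
def _trace_rays(srcx, srcy, detx, dety, nx, ny, px, indptr, indices, data):
    """Trace all rays; fill CSR arrays. Returns total entry count."""
    x0 = -0.5 * nx * px
    ytop = 0.5 * ny * px
    ptr = 0
    n_rays = srcx.size
    for r in range(n_rays):
        indptr[r] = ptr
        sx = srcx[r]
        sy = srcy[r]
        dx = detx[r] - sx
        dy = dety[r] - sy
        norm = np.sqrt(dx * dx + dy * dy)
        if norm == 0.0:
            continue
        # clip the forward half-line t >= 0 against the grid bounding box
        t0 = 0.0
        t1 = 1.0e30
        ok = True
        if dx != 0.0:
            ta = (x0 - sx) / dx
            tb = (x0 + nx * px - sx) / dx
            lo = min(ta, tb)
            hi = max(ta, tb)
            t0 = max(t0, lo)
            t1 = min(t1, hi)
        elif sx <= x0 or sx >= x0 + nx * px:
            ok = False
        if dy != 0.0:
            ta = (ytop - ny * px - sy) / dy
            tb = (ytop - sy) / dy
            lo = min(ta, tb)
            hi = max(ta, tb)
            t0 = max(t0, lo)
            t1 = min(t1, hi)
        elif sy <= ytop - ny * px or sy >= ytop:
            ok = False
        if (not ok) or t0 >= t1:
            continue
        # entry cell
        xin = sx + t0 * dx
        yin = sy + t0 * dy
        ix = int(np.floor((xin - x0) / px))
        iy = int(np.floor((ytop - yin) / px))  # image row index
        if ix < 0:
            ix = 0
        if ix > nx - 1:
            ix = nx - 1
        if iy < 0:
            iy = 0
        if iy > ny - 1:
            iy = ny - 1
        big = 1.0e30
        if dx > 0.0:
            stepx = 1
            tmaxx = (x0 + (ix + 1) * px - sx) / dx
            tdx = px / dx
        elif dx < 0.0:
            stepx = -1
            tmaxx = (x0 + ix * px - sx) / dx
            tdx = -px / dx
        else:
            stepx = 0
            tmaxx = big
            tdx = big
        # row index increases as y decreases
        if dy < 0.0:
            stepy = 1
            tmaxy = (ytop - (iy + 1) * px - sy) / dy
            tdy = -px / dy
        elif dy > 0.0:
            stepy = -1
            tmaxy = (ytop - iy * px - sy) / dy
            tdy = px / dy
        else:
            stepy = 0
            tmaxy = big
            tdy = big
        t = t0
        eps = 1.0e-12 * (1.0 + t1)
        while t < t1 - eps:
            tnext = tmaxx if tmaxx < tmaxy else tmaxy
            if tnext > t1:
                tnext = t1
            seg = (tnext - t) * norm
            if seg > 0.0:
                indices[ptr] = iy * nx + ix
                data[ptr] = seg
                ptr += 1
            if tnext >= t1 - eps:
                break
            if tmaxx <= tnext + eps:
                ix += stepx
                tmaxx += tdx
            if tmaxy <= tnext + eps:
                iy += stepy
                tmaxy += tdy
            if ix < 0 or ix >= nx or iy < 0 or iy >= ny:
                break
            t = tnext
    indptr[n_rays] = ptr
    return ptr


@dataclass
class SystemMatrix:
    """Sparse ray–pixel intersection-length operator with its geometry."""

    H: sp.csr_matrix
    grid: ImageGrid
    geometry: FanBeamGeometry

    @property
    def shape(self) -> tuple[int, int]:
        return self.H.shape

    def dot(self, x: np.ndarray) -> np.ndarray:
        return self.H @ x

    def rdot(self, p: np.ndarray) -> np.ndarray:
        return self.H.T @ p

    def row_sums(self) -> np.ndarray:
        """Total intersection length of each ray with the grid support (mm)."""
        return np.asarray(self.H.sum(axis=1)).ravel()


def build_system_matrix(grid: ImageGrid, geometry: FanBeamGeometry) -> SystemMatrix:
    """Trace every ray through the grid and assemble the sparse matrix.

    Deterministic for fixed inputs.  Raises if the source orbit passes
    through the grid support (the ray parameterization starts at the
    source, which must be outside the image).
    """
    w, h = grid.extent_mm
    half = float(np.hypot(w, h)) / 2.0
    if geometry.source_to_iso_mm <= half:
        raise ValueError(
            "X-ray source lies inside (or on) the grid support; "
            "fan-beam ray tracing requires the source outside the image"
        )
    src, det = geometry.ray_endpoints()
    n_rays = src.shape[0]
    cap = n_rays * (grid.nx + grid.ny + 3)
    indptr = np.zeros(n_rays + 1, dtype=np.int64)
    indices = np.empty(cap, dtype=np.int64)
    data = np.empty(cap, dtype=np.float64)
    nnz = _trace_rays(
        np.ascontiguousarray(src[:, 0]),
        np.ascontiguousarray(src[:, 1]),
        np.ascontiguousarray(det[:, 0]),
        np.ascontiguousarray(det[:, 1]),
        grid.nx,
        grid.ny,
        grid.pixel_size_mm,
        indptr,
        indices,
        data,
    )
    H = sp.csr_matrix(
        (data[:nnz].copy(), indices[:nnz].copy(), indptr),
        shape=(n_rays, grid.n_pixels),
    )
    return SystemMatrix(H=H, grid=grid, geometry=geometry)


def forward_project(A: SystemMatrix, image: np.ndarray) -> np.ndarray:
    """Apply H: image (flat N or (ny, nx)) -> sinogram values (n_views, n_bins)."""
    x = np.asarray(image, dtype=float).ravel()
    if x.size != A.grid.n_pixels:
        raise ValueError(f"image has {x.size} pixels, grid expects {A.grid.n_pixels}")
    p = A.H @ x
    return p.reshape(A.geometry.n_views, A.geometry.n_bins)


def back_project(A: SystemMatrix, sino_values: np.ndarray) -> np.ndarray:
    """Apply Hᵀ: sinogram values (flat M or (n_views, n_bins)) -> flat image."""
    p = np.asarray(sino_values, dtype=float).ravel()
    if p.size != A.geometry.n_rays:
        raise ValueError(f"sinogram has {p.size} rays, geometry expects {A.geometry.n_rays}")
    return A.H.T @ p


def save_system_matrix(A: SystemMatrix, path) -> None:
    """Write the sparse structure plus grid/geometry metadata to one file."""
    meta = {
        "version": _CACHE_VERSION,
        "grid": A.grid.to_dict(),
        "geometry": A.geometry.to_dict(),
        "geometry_hash": A.geometry.content_hash(),
    }
    np.savez(
        path,
        indptr=A.H.indptr,
        indices=A.H.indices,
        data=A.H.data,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_system_matrix(
    path,
    grid: ImageGrid | None = None,
    geometry: FanBeamGeometry | None = None,
) -> SystemMatrix:
    """Load a cached matrix; reject stale or mismatched caches."""
    with np.load(path) as f:
        meta = json.loads(bytes(f["meta"].tobytes()).decode())
        if meta.get("version") != _CACHE_VERSION:
            raise ValueError(
                f"system-matrix cache version {meta.get('version')!r} does not match "
                f"{_CACHE_VERSION!r}; rebuild the cache"
            )
        g = ImageGrid(**meta["grid"])
        geo_d = meta["geometry"]
        geo = FanBeamGeometry(
            n_views=geo_d["n_views"],
            n_bins=geo_d["n_bins"],
            source_to_iso_mm=geo_d["source_to_iso_mm"],
            source_to_detector_mm=geo_d["source_to_detector_mm"],
            bin_spacing_mm=geo_d["bin_spacing_mm"],
            view_angles_rad=np.asarray(geo_d["view_angles_rad"]),
        )
        if grid is not None and grid.to_dict() != g.to_dict():
            raise ValueError("cached system matrix was built for a different grid")
        if geometry is not None and geometry.content_hash() != meta["geometry_hash"]:
            raise ValueError("cached system matrix was built for a different geometry")
        H = sp.csr_matrix(
            (f["data"], f["indices"], f["indptr"]),
            shape=(geo.n_rays, g.n_pixels),
        )
    return SystemMatrix(H=H, grid=g, geometry=geo)
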