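"""Ellipse-composite head phantom and analytic fan-beam line integrals.

A synthetic, fully parametric stand-in for licensed anthropomorphic
phantoms: a skull-like outer ellipse, a brain-tissue interior, ventricles
and three low-contrast lesions, with named ROIs (A/B/C + background) for
contrast and similarity metrics.  Attenuation values sit in the soft-tissue
range so the standard display window [0.0048, 0.0128] mm^-1 applies.

Line integrals through the composite are available in closed form (sum of
attenuation times line–ellipse chord length per ellipse), which provides
noise-free sinograms free of the inverse crime of projecting the
rasterized image with the same discrete operator used for reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import FanBeamGeometry, ImageGrid, Sinogram
from .metrics import ROISpec

__all__ = [
    "Ellipse",
    "PhantomSpec",
    "rasterize_phantom",
    "analytic_sinogram",
    "default_head_phantom",
]


@dataclass(frozen=True)
class Ellipse:
    """center (mm), semi-axes (mm), CCW rotation (rad), additive value (mm^-1)."""

    cx: float
    cy: float
    a: float
    b: float
    theta: float
    value: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError("ellipse semi-axes must be positive")


@dataclass
class PhantomSpec:
    """Additive ellipse composite plus named metric ROIs."""

    ellipses: list
    rois: list = field(default_factory=list)
    seed: int = 0

    def roi(self, name: str) -> ROISpec:
        for r in self.rois:
            if r.name == name:
                return r
        raise KeyError(f"no ROI named {name!r}")


def _to_ellipse_frame(e: Ellipse, px: np.ndarray, py: np.ndarray):
    """Map physical coordinates into the ellipse's unit-circle frame."""
    c, s = np.cos(e.theta), np.sin(e.theta)
    dx = px - e.cx
    dy = py - e.cy
    return (c * dx + s * dy) / e.a, (-s * dx + c * dy) / e.b


def rasterize_phantom(spec: PhantomSpec, grid: ImageGrid) -> np.ndarray:
    """Flat ground-truth image: sum of ellipse values at each pixel center."""
    X, Y = grid.pixel_centers()
    img = np.zeros(X.shape)
    for e in spec.ellipses:
        u, v = _to_ellipse_frame(e, X, Y)
        img[u * u + v * v <= 1.0] += e.value
    return img.ravel()


def analytic_sinogram(spec: PhantomSpec, geometry: FanBeamGeometry) -> Sinogram:
    """Exact line integrals: per-ellipse closed-form chord lengths."""
    src, det = geometry.ray_endpoints()
    vals = np.zeros(src.shape[0])
    seg = det - src
    seg_len = np.linalg.norm(seg, axis=1)
    for e in spec.ellipses:
        su, sv = _to_ellipse_frame(e, src[:, 0], src[:, 1])
        du, dv = _to_ellipse_frame(e, det[:, 0], det[:, 1])
        wu, wv = du - su, dv - sv
        # |s' + t w|^2 = 1  ->  (w.w) t^2 + 2 (s'.w) t + (s'.s' - 1) = 0
        A = wu * wu + wv * wv
        B = su * wu + sv * wv
        C = su * su + sv * sv - 1.0
        disc = B * B - A * C
        hit = (disc > 0) & (A > 0)
        dt = np.zeros_like(vals)
        dt[hit] = 2.0 * np.sqrt(disc[hit]) / A[hit]
        vals += e.value * dt * seg_len
    return Sinogram(vals.reshape(geometry.n_views, geometry.n_bins), geometry)


def default_head_phantom(grid: ImageGrid) -> PhantomSpec:
    """Deterministic head-like phantom scaled to the grid's physical size.

    Skull ring at 0.025 mm^-1, brain tissue at 0.0096 mm^-1, two darker
    ventricles, and three low-contrast lesions (A: +12%, B: +8%, C: +4%
    over brain tissue).  ROIs are squares spanning ~80% of each lesion
    radius (so a few boundary pixels keep region variances finite), plus a
    uniform background ROI.
    """
    half = 0.5 * min(grid.extent_mm)  # mm
    skull, brain = 0.025, 0.0096
    ellipses = [
        Ellipse(0.0, 0.0, 0.88 * half, 0.96 * half, 0.0, skull),
        Ellipse(0.0, 0.0, 0.78 * half, 0.87 * half, 0.0, brain - skull),
        Ellipse(-0.20 * half, 0.22 * half, 0.09 * half, 0.22 * half, 0.25, -0.0020),
        Ellipse(0.20 * half, 0.22 * half, 0.09 * half, 0.22 * half, -0.25, -0.0020),
        Ellipse(-0.32 * half, -0.34 * half, 0.10 * half, 0.10 * half, 0.0, 0.0012),  # A
        Ellipse(0.02 * half, -0.47 * half, 0.09 * half, 0.09 * half, 0.0, 0.0008),  # B
        Ellipse(0.34 * half, -0.30 * half, 0.10 * half, 0.10 * half, 0.0, 0.0004),  # C
    ]

    def _roi_square(name: str, cx_mm: float, cy_mm: float, half_mm: float) -> ROISpec:
        px = grid.pixel_size_mm
        col = (cx_mm / px) + (grid.nx - 1) / 2.0
        row = (grid.ny - 1) / 2.0 - (cy_mm / px)
        hw = max(int(round(half_mm / px)), 2)
        r0, c0 = int(round(row)) - hw, int(round(col)) - hw
        return ROISpec(name, rect=(r0, c0, r0 + 2 * hw, c0 + 2 * hw))

    rois = [
        _roi_square("ROIA", -0.32 * half, -0.34 * half, 0.08 * half),
        _roi_square("ROIB", 0.02 * half, -0.47 * half, 0.072 * half),
        _roi_square("ROIC", 0.34 * half, -0.30 * half, 0.08 * half),
        _roi_square("Background", 0.0, 0.05 * half, 0.10 * half),
    ]
    return PhantomSpec(ellipses=ellipses, rois=rois, seed=0)
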