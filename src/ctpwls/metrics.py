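"""Quantitative image-quality metrics: SNR, MSE, CNR, UQI.

SNR and MSE compare a reconstruction against the ground-truth phantom over
the full grid; CNR contrasts a region of interest against a background
region of the same image; UQI measures similarity against the truth within
an ROI, combining correlation, luminance and contrast agreement into one
score in [-1, 1] (1 = identical up to sampling).  Variances and
covariances use the sample (Q - 1) denominator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ROISpec", "MetricsReport", "snr_db", "mse", "cnr", "uqi"]


@dataclass
class ROISpec:
    """Named image region: a boolean mask or a half-open pixel rectangle.

    ``rect`` is (row0, col0, row1, col1) with 0-based half-open ranges.
    """

    name: str
    rect: tuple[int, int, int, int] | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.rect is None) == (self.mask is None):
            raise ValueError("provide exactly one of rect or mask")
        if self.rect is not None:
            r0, c0, r1, c1 = self.rect
            if not (r0 < r1 and c0 < c1) or min(r0, c0) < 0:
                raise ValueError(f"degenerate ROI rectangle {self.rect}")

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        if self.mask is not None:
            if self.mask.shape != shape:
                raise ValueError("ROI mask shape does not match the image")
            m = self.mask.astype(bool)
        else:
            r0, c0, r1, c1 = self.rect
            if r1 > shape[0] or c1 > shape[1]:
                raise ValueError(f"ROI {self.name!r} exceeds the grid bounds {shape}")
            m = np.zeros(shape, dtype=bool)
            m[r0:r1, c0:c1] = True
        if not m.any():
            raise ValueError(f"ROI {self.name!r} is empty")
        return m

    def extract(self, image: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
        return np.asarray(image).reshape(shape)[self.to_mask(shape)]


def snr_db(x: np.ndarray, x_true: np.ndarray) -> float:
    """10 log10( sum x_true^2 / sum (x_true - x)^2 ); +inf if identical."""
    x = np.asarray(x, dtype=float).ravel()
    xt = np.asarray(x_true, dtype=float).ravel()
    if x.size != xt.size:
        raise ValueError("images must have the same size")
    if not np.any(xt):
        raise ValueError("reference image is identically zero")
    err = float(np.sum((xt - x) ** 2))
    if err == 0.0:
        return float("inf")
    return float(10.0 * np.log10(np.sum(xt * xt) / err))


def mse(x: np.ndarray, x_true: np.ndarray) -> float:
    x = np.asarray(x, dtype=float).ravel()
    xt = np.asarray(x_true, dtype=float).ravel()
    if x.size != xt.size:
        raise ValueError("images must have the same size")
    return float(np.mean((xt - x) ** 2))


def cnr(image: np.ndarray, roi: ROISpec, bg: ROISpec, shape: tuple[int, int] | None = None) -> float:
    """|mean_ROI - mean_BG| / sqrt(var_ROI + var_BG)."""
    img = np.asarray(image, dtype=float)
    if shape is None:
        if img.ndim != 2:
            raise ValueError("pass shape= for flat images")
        shape = img.shape
    a = roi.extract(img, shape)
    b = bg.extract(img, shape)
    if a.size < 2 or b.size < 2:
        raise ValueError("CNR regions need at least 2 pixels each")
    va = float(np.var(a, ddof=1))
    vb = float(np.var(b, ddof=1))
    if va + vb == 0.0:
        raise ValueError("CNR undefined: both region variances are zero")
    return float(abs(a.mean() - b.mean()) / np.sqrt(va + vb))


def uqi(x: np.ndarray, x_true: np.ndarray, roi: ROISpec, shape: tuple[int, int] | None = None) -> float:
    """Universal quality index over the ROI:

    4 Cov(x, xt) xbar xtbar / ((var + var_t)(xbar^2 + xtbar^2)).
    """
    img = np.asarray(x, dtype=float)
    imgt = np.asarray(x_true, dtype=float)
    if shape is None:
        if img.ndim != 2:
            raise ValueError("pass shape= for flat images")
        shape = img.shape
    a = roi.extract(img, shape)
    b = roi.extract(imgt, shape)
    if a.size < 2:
        raise ValueError("UQI region needs at least 2 pixels")
    if np.array_equal(a, b):
        return 1.0  # identical regions: perfect similarity (0/0 limit)
    ma, mb = float(a.mean()), float(b.mean())
    va = float(np.var(a, ddof=1))
    vb = float(np.var(b, ddof=1))
    cov = float(np.sum((b - mb) * (a - ma)) / (a.size - 1))
    denom = (va + vb) * (ma * ma + mb * mb)
    if denom == 0.0:
        raise ValueError("UQI undefined: zero denominator on this ROI")
    return float(4.0 * cov * ma * mb / denom)


@dataclass
class MetricsReport:
    """Full-grid SNR/MSE plus per-ROI CNR and UQI for one reconstruction."""

    snr_db: float
    mse: float
    cnr: dict = field(default_factory=dict)
    uqi: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "snr_db": self.snr_db,
            "mse": self.mse,
            "cnr": dict(self.cnr),
            "uqi": dict(self.uqi),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=2)
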