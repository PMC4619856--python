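"""Image grid and fan-beam scanner geometry.

Conventions (shared by every module):

* Images are stored row-major with pixel ``(0, 0)`` at the top-left of the
  array.  Physical ``x`` increases with the column index (rightward) and
  physical ``y`` increases upward, so the row index runs against ``y``.
* The isocenter (rotation center) sits at the center of the grid.
* A view angle is measured counter-clockwise from the +x axis to the
  *source* position.
* The detector is modelled as a flat (equidistant) virtual detector placed
  on the line through the isocenter, perpendicular to the source direction.
  Bin spacing given at the physical detector is rescaled onto this virtual
  detector by the magnification ``source_to_iso / source_to_detector``.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageGrid", "FanBeamGeometry", "Sinogram"]


@dataclass(frozen=True)
class ImageGrid:
    """Square-pixel reconstruction grid centered on the isocenter."""

    nx: int
    ny: int
    pixel_size_mm: float

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must have at least one pixel per axis")
        if not self.pixel_size_mm > 0:
            raise ValueError("pixel_size_mm must be positive")

    @property
    def n_pixels(self) -> int:
        return self.nx * self.ny

    @property
    def extent_mm(self) -> tuple[float, float]:
        """Physical (width, height) of the grid in mm."""
        return (self.nx * self.pixel_size_mm, self.ny * self.pixel_size_mm)

    @property
    def diagonal_mm(self) -> float:
        w, h = self.extent_mm
        return float(np.hypot(w, h))

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x, y) coordinates of pixel centers, shape (ny, nx) each."""
        px = self.pixel_size_mm
        xs = (np.arange(self.nx) - (self.nx - 1) / 2.0) * px
        ys = ((self.ny - 1) / 2.0 - np.arange(self.ny)) * px
        return np.meshgrid(xs, ys)

    def to_dict(self) -> dict:
        return {"nx": self.nx, "ny": self.ny, "pixel_size_mm": self.pixel_size_mm}


@dataclass(frozen=True)
class FanBeamGeometry:
    """Circular-orbit fan-beam geometry with a flat equidistant detector.

    ``bin_spacing_mm`` is the spacing at the physical detector; rays are
    parameterized through the virtual detector at the isocenter where the
    spacing is ``bin_spacing_mm * source_to_iso_mm / source_to_detector_mm``.
    """

    n_views: int
    n_bins: int
    source_to_iso_mm: float
    source_to_detector_mm: float
    bin_spacing_mm: float
    view_angles_rad: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_views < 1 or self.n_bins < 1:
            raise ValueError("n_views and n_bins must be positive")
        if not (self.source_to_detector_mm > self.source_to_iso_mm > 0):
            raise ValueError("require source_to_detector_mm > source_to_iso_mm > 0")
        if not self.bin_spacing_mm > 0:
            raise ValueError("bin_spacing_mm must be positive")
        if self.view_angles_rad is None:
            angles = np.arange(self.n_views) * (2.0 * np.pi / self.n_views)
        else:
            angles = np.asarray(self.view_angles_rad, dtype=float)
            if angles.shape != (self.n_views,):
                raise ValueError("view_angles_rad must have length n_views")
            if np.any(np.diff(angles) <= 0):
                raise ValueError("view angles must be strictly increasing")
        object.__setattr__(self, "view_angles_rad", angles)

    @property
    def n_rays(self) -> int:
        return self.n_views * self.n_bins

    @property
    def iso_bin_spacing_mm(self) -> float:
        """Detector bin spacing rescaled to the virtual detector at isocenter."""
        return self.bin_spacing_mm * self.source_to_iso_mm / self.source_to_detector_mm

    def bin_offsets_mm(self) -> np.ndarray:
        """Signed bin-center offsets along the virtual detector, length n_bins."""
        return (np.arange(self.n_bins) - (self.n_bins - 1) / 2.0) * self.iso_bin_spacing_mm

    def source_positions(self) -> np.ndarray:
        """(n_views, 2) source (x, y) positions in mm."""
        a = self.view_angles_rad
        return self.source_to_iso_mm * np.stack([np.cos(a), np.sin(a)], axis=1)

    def ray_endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-ray (source, virtual-detector point) coordinates.

        Returns two arrays of shape (n_views * n_bins, 2), ray index ordered
        view-major (ray = view * n_bins + bin).
        """
        a = self.view_angles_rad
        src = self.source_positions()
        # detector axis: unit vector perpendicular to the source direction
        ex, ey = -np.sin(a), np.cos(a)
        t = self.bin_offsets_mm()
        dx = t[None, :] * ex[:, None]
        dy = t[None, :] * ey[:, None]
        det = np.stack([dx, dy], axis=2).reshape(-1, 2)
        srcs = np.repeat(src, self.n_bins, axis=0)
        return srcs, det

    def to_dict(self) -> dict:
        return {
            "n_views": self.n_views,
            "n_bins": self.n_bins,
            "source_to_iso_mm": self.source_to_iso_mm,
            "source_to_detector_mm": self.source_to_detector_mm,
            "bin_spacing_mm": self.bin_spacing_mm,
            "view_angles_rad": np.asarray(self.view_angles_rad).tolist(),
        }

    def content_hash(self) -> str:
        return _hash_dict(self.to_dict())


def _hash_dict(d: dict) -> str:
    return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class Sinogram:
    """Post-log line-integral data, shape (n_views, n_bins), units mm^-1 * mm."""

    values: np.ndarray
    geometry: FanBeamGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expect = (self.geometry.n_views, self.geometry.n_bins)
        if self.values.shape != expect:
            raise ValueError(f"sinogram shape {self.values.shape} != geometry {expect}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram contains non-finite values")

    def ravel(self) -> np.ndarray:
        return self.values.ravel()
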