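"""Forward-project a uniform disk and reconstruct it with fan-beam FBP.

Builds the exact intersection-length system matrix for a small fan-beam
geometry, projects a 50 mm disk of attenuation 0.01 /mm, and checks the
filtered back-projection round trip.
"""

import numpy as np

from ctpwls import (
    Ellipse,
    FanBeamGeometry,
    ImageGrid,
    PhantomSpec,
    analytic_sinogram,
    build_system_matrix,
    fbp_reconstruct,
    forward_project,
    rasterize_phantom,
)

grid = ImageGrid(nx=128, ny=128, pixel_size_mm=1.25)
geom = FanBeamGeometry(
    n_views=180, n_bins=256, source_to_iso_mm=570.0, source_to_detector_mm=1040.0, bin_spacing_mm=1.407
)
disk = PhantomSpec(ellipses=[Ellipse(0, 0, 50.0, 50.0, 0.0, 0.01)])

A = build_system_matrix(grid, geom)
print(f"system matrix: {A.shape[0]} rays x {A.shape[1]} pixels, {A.H.nnz} nonzeros")

sino_exact = analytic_sinogram(disk, geom)
sino_discrete = forward_project(A, rasterize_phantom(disk, grid))
rel = np.linalg.norm(sino_discrete - sino_exact.values) / np.linalg.norm(sino_exact.values)
print(f"discrete vs analytic line integrals: relative l2 difference {rel:.4f}")
print("  (discretization error of the rasterized phantom; shrinks with finer pixels)")

img = fbp_reconstruct(sino_exact, grid).reshape(grid.ny, grid.nx)
X, Y = grid.pixel_centers()
interior = (X**2 + Y**2) <= 40.0**2
print(f"FBP disk interior mean: {img[interior].mean():.6f} /mm (truth 0.010000)")
print("  an accurate round trip validates weighting, ramp filter and back-projection")
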