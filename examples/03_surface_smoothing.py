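"""Surface smoothing calibrated to a Gaussian FWHM.

Per-vertex maps are smoothed by repeatedly averaging each vertex with its
mesh neighbors.  The iteration count is calibrated so the response to a
point impulse has the requested full width at half maximum (FWHM) measured
in geodesic millimetres along the surface.
"""

import numpy as np

from gwrkit import (
    SmootherConfig,
    VertexMap,
    calibrate_iterations,
    icosphere,
    measure_kernel_fwhm,
    smooth_map,
)

mesh = icosphere(5, 100.0)  # fine sphere: 10242 vertices, ~3.3 mm edges
for fwhm in (10.0, 20.0, 30.0):
    n = calibrate_iterations(mesh, fwhm)
    measured = measure_kernel_fwhm(mesh, n)
    print(f"requested {fwhm:5.1f} mm -> {n:3d} iterations, "
          f"half-max width {measured:5.1f} mm")

# Smoothing shrinks noise roughly like averaging over the kernel footprint.
rng = np.random.default_rng(0)
noisy = VertexMap(rng.normal(0.0, 1.0, size=mesh.n_vertices))
smoothed = smooth_map(noisy, mesh, SmootherConfig(fwhm=30.0))
print(f"noise SD before {noisy.values.std():.3f}, after {smoothed.values.std():.3f}")
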