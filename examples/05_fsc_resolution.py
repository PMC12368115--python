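"""Estimate image resolution with Fourier shell correlation.

Builds a synthetic structure (a spherical shell of radius 300 nm observed
with 30 nm localisation jitter), randomly splits the localisations in two,
voxelises and blurs both halves, and reads the resolution at the first
descent of the shell correlation through the 1/7 threshold.  A uniform
point cloud of the same size serves as an unstructured reference: its
correlation collapses immediately, giving a much worse resolution.
"""

import numpy as np
import pandas as pd

from dhpsf import fsc_resolution

rng = np.random.default_rng(3)
n = 4000


def shell_points():
    phi = rng.uniform(0, 2 * np.pi, n)
    cos_t = rng.uniform(-1, 1, n)
    sin_t = np.sqrt(1 - cos_t ** 2)
    return pd.DataFrame({
        "x_nm": 300 * sin_t * np.cos(phi) + rng.normal(0, 30, n) + 400,
        "y_nm": 300 * sin_t * np.sin(phi) + rng.normal(0, 30, n) + 400,
        "z_nm": 300 * cos_t + rng.normal(0, 30, n) + 400,
    })


structured = shell_points()
uniform = pd.DataFrame({c: rng.uniform(0, 800, n)
                        for c in ("x_nm", "y_nm", "z_nm")})

res_s = fsc_resolution(structured, voxel_nm=5.0, seed=1)
res_u = fsc_resolution(uniform, voxel_nm=5.0, seed=1)
print(f"structured shell: FSC resolution {res_s.resolution_nm:.0f} nm "
      f"(halves {res_s.n_half1}/{res_s.n_half2})")
print(f"uniform cloud:    FSC resolution {res_u.resolution_nm:.0f} nm")
print("the structured set retains correlation out to much higher spatial "
      "frequency, hence the finer resolution")
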