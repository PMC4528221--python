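"""Spherical-spline surface Laplacian sanity checks.

A spatially constant potential has zero Laplacian; a degree-1 spherical
harmonic is an eigenfunction of the surface Laplacian with eigenvalue
-1*(1+1) = -2, which the spline operator reproduces at the electrodes.
"""

import numpy as np

from erdswitch import DEFAULT_EEG_CHANNELS, standard_montage
from erdswitch.spatial_filter import laplacian_transform

montage = standard_montage(DEFAULT_EEG_CHANNELS)
T = laplacian_transform(montage)

const = np.full(30, 10.0)
print(f"constant 10 uV input -> max |Laplacian| = {np.abs(T @ const).max():.2e}")

harmonic = montage.positions[:, 0]  # x-coordinate = degree-1 harmonic
out = T @ harmonic
slope = (out @ (-2 * harmonic)) / ((-2 * harmonic) @ (-2 * harmonic))
print(f"degree-1 harmonic: fitted scale vs analytic eigenvalue -2: {slope:.4f}")
print(f"worst channel deviation: "
      f"{np.abs(out + 2 * harmonic).max() / np.abs(2 * harmonic).max():.2%}")
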