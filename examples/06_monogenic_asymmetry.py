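"""Monogenic phase-asymmetry map of a synthetic volume.

A log-Gabor band-pass plus the Riesz transform splits the image into even and
odd parts; the asymmetry map R peaks on step-like interfaces and vanishes on
even-symmetric ridges, which makes it a contrast-invariant edge feature for
guiding ultrasound registration (compared between volumes with NCC).
"""

import numpy as np

from fetalmorph.monogenic import Volume3D, monogenic_decompose, ncc, phase_asymmetry

n = 48
x = np.arange(n)
# a smooth step interface (like a tissue boundary) and an even-symmetric ridge
step = 0.5 * (1 + np.tanh((x - n / 2) / 1.5))
ridge = np.exp(-((x - n / 2) ** 2) / (2 * 1.5**2))
vol_step = Volume3D(np.broadcast_to(step[:, None, None], (n, n, n)).copy(), spacing=[0.5] * 3)
vol_ridge = Volume3D(np.broadcast_to(ridge[:, None, None], (n, n, n)).copy(), spacing=[0.5] * 3)

R_step = phase_asymmetry(monogenic_decompose(vol_step, center_wavelength_mm=6.0), T=0.5).R
R_ridge = phase_asymmetry(monogenic_decompose(vol_ridge, center_wavelength_mm=6.0), T=0.5).R

interior = slice(n // 4, 3 * n // 4)
profile = R_step[interior, n // 2, n // 2]
peak_plane = n // 4 + int(np.argmax(profile))
print(f"step volume: asymmetry peaks on plane {peak_plane} (interface at {n // 2})")
print(f"R at the interface: {R_step[n // 2, n // 2, n // 2]:.3f}; "
      f"R on the ridge's central plane: {R_ridge[n // 2].max():.3f}")

brighter = Volume3D(10.0 * vol_step.data + 50.0, spacing=[0.5] * 3)
R_bright = phase_asymmetry(monogenic_decompose(brighter, 6.0), T=0.5).R
print(f"NCC between original and rescaled-intensity maps: {ncc(R_step, R_bright):.4f}")

# The asymmetry map localizes the step interface and stays ~0 on the
# even-symmetric ridge; it is unchanged by global intensity scaling/offset
# (NCC = 1), which is why it is a robust similarity channel for
# registration-based segmentation.
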