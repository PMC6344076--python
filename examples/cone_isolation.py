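"""Silent-substitution stimulus design with three LEDs.

Builds the LED-to-isomerization matrix from pigment nomograms (λmax
430/531/561 nm) and Gaussian LED spectra (406/515/640 nm), then solves for
drive modulations that put 30% contrast on S cones while holding M and L
cones exactly constant.
"""

import numpy as np

from conephys.isolation import (
    ConeIsolationMatrix,
    cone_isolating_stimulus,
    isomerization_rate,
)

matrix = ConeIsolationMatrix.default()
print("LED -> isomerization matrix (rows S/M/L, columns 406/515/640 nm):")
print(np.array_str(matrix.matrix, precision=4))

mean_drives = np.ones(3)
drives = cone_isolating_stimulus(np.array([0.3, 0.0, 0.0]), matrix, mean_drives)
rates = isomerization_rate(drives, matrix)
mean_rates = matrix.matrix @ mean_drives
contrast = (rates - mean_rates[:, None]) / mean_rates[:, None]

for i, cone in enumerate("SML"):
    print(f"{cone}-cone contrast over the two stimulus phases: "
          f"{contrast[i, 0]:+.2e} / {contrast[i, 1]:+.2e}")

print("\nThe S row swings ±0.30 while M and L stay at zero to numerical "
      "precision: the\nmodulation is invisible to the cone types being "
      "silenced.")
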