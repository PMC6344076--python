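"""Flash-response kinetics of simulated S vs L/M cones.

Builds small populations of synthetic cones at a 5000 R*/s background,
averages their flash trials, and measures time to peak and FWHM with the
truncated-Gaussian estimator.  S cones should come out ~9 ms slower and
~5-7 ms broader than L and M cones.
"""

from conephys import ensembles
from conephys.pipeline import kinetics_report

for cone_type in ("S", "M", "L"):
    recs = ensembles.flash_ensemble(cone_type, 5000.0, n_cells=8, n_trials=10,
                                    seed=0)
    rep = kinetics_report(recs)
    print(
        f"{cone_type} cones (n={len(rep)}): "
        f"time to peak {rep.time_to_peak_ms.mean():.1f} ms, "
        f"FWHM {rep.fwhm_ms.mean():.1f} ms"
    )

print("\nEach line is an ensemble mean over simulated cells; the S-cone "
      "response peaks later\nand lasts longer than the L/M responses, the "
      "kinetic signature this package measures.")
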