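"""LN-model estimation for a simulated small bistratified cell (SBC).

Simulates spike trains driven by an LM-OFF linear filter at two background
light levels, re-estimates the filters by regularised reverse correlation
from the binary spike vectors, fits the flash template to each filter, and
reports the background-induced peak-time shift.
"""

from conephys import ensembles
from conephys.pipeline import sbc_report

cells = ensembles.sbc_ensemble("lm_off", n_cells=2, seed=0, duration=300.0)
rep = sbc_report(cells)

print(rep.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print("\npeak_low/peak_high are the filter peak times at 1000 and 10,000 "
      "R*/s; the ~10 ms shift\nshows LM-cone-driven responses speeding up "
      "with background, the adaptation signature\nthat S-cone-driven "
      "responses largely lack.")
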