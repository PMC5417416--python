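"""Map the dynamical regimes of the cortical sheet.

Sweeps the excitatory baseline drive P at the operating Q and classifies
each point as background / bistable / seizure by integrating the coupled
sheet from a quiescent and from an established-seizure initial condition.
"""

import numpy as np

import ictalsheet as ish

grid = np.round(np.arange(-3.0, -0.79, 0.1), 10)
print(" P      state")
for P in grid:
    print(f"{P:+.1f}   {ish.classify_state(float(P)).label}")

lo, hi = ish.bistable_band(P_grid=grid)
print(f"\nBistable band: ({lo}, {hi})")
print("Inside this band a seizure state (sustained re-entrant waves) "
      "coexists with the quiescent background; a local trigger is enough "
      "to flip the sheet. Below it waves die out, above it the background "
      "itself is unstable.")
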