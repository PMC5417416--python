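"""Tracking hidden excitability with active probing.

The sheet's baseline ECoG barely changes as the global drive P climbs from
deep background toward the bistable regime - the rising excitability is
electrographically latent.  Brief focal stimulation pulses reveal it: the
probe response amplitude tracks the drive.
"""

import ictalsheet as ish

tr = ish.run_excitability_tracking(seed=1)
print("level (P)   mean probe response (a.u.)")
import numpy as np
for lev in tr["levels"]:
    sel = tr["P_at_cycle"] == lev
    if sel.any():
        print(f"{lev:+.3f}     {np.nanmean(tr['response']['mean'][sel]):.2f}")
print(f"\nPearson r(P, response) = {tr['pearson_r']:.3f} "
      f"(p = {tr['pearson_p']:.1e}, {tr['cycles_used']} cycles)")
if tr["seizure_triggered"]:
    print("A probe pulse eventually triggered a global seizure at the "
          "highest excitability - flagged, and later cycles excluded.")
print("The response amplitude rises monotonically with the hidden drive: "
      "stimulation probing can monitor excitability that passive "
      "recordings cannot see.")
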