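"""Onset amplitude across surround excitability.

A small slice of the parameter scan: the same microdomain protocol run at
a monostable (-4) and a bistable (-1.5) surround drive, for one and many
patches.  High-amplitude onsets live where the surround is bistable.
"""

import ictalsheet as ish

geom = ish.SheetGeometry(n_rows=60, n_cols=60)
df = ish.run_parameter_scan(P_grid=[-4.0, -1.5], percent_grid=(5.0,),
                            n_patches_grid=(1, 15), n_random_configs=2,
                            geometry=geom, seed=3)
table = df.groupby(["axis_value", "n_patches"])[
    ["onset_amplitude", "onset_frequency"]].mean().round(2)
print(table)
print("\nAmplitudes are in units of the low-amplitude-fast reference "
      "onset (~1). The bistable surround (-1.5) produces the large "
      "onsets; in the monostable surround the many-patch configuration "
      "is less coordinated and appears smaller than a single patch.")
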