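# ictalsheet

A spatio-temporal model of focal seizure onset: a 150×150 lattice of
stochastic Wilson–Cowan minicolumns with local feed-forward excitation,
local feed-forward inhibition and patchy long-range excitation.  The
package reproduces, end to end, the two canonical ECoG onset patterns of
focal seizures and the experiments built on them:

* **LAF** (low amplitude fast): many small "microseizure" domains inside a
  weakly excitable surround — onset appears as low-amplitude beta-range
  oscillation that grows as the domains coalesce;
* **HAS** (high amplitude slow): a single domain inside a *bistable*
  surround — one local trigger flips the whole sheet into a coexisting
  seizure state, producing a high-amplitude sub-alpha rhythm with
  near-instant recruitment;
* surround-excitability parameter scans, in-silico resection of the onset
  zone, and excitability tracking by active stimulation probing.

It is intended for computational neuroscientists studying seizure onset
mechanisms, recruitment dynamics and stimulation-based excitability
mapping in neural-mass sheet models.

## Model

Each minicolumn is a Wilson–Cowan pair

```
τ_E dE/dt = −E + Sigm(C_EE·E + C_IE·I + P + A_s·S(t) + lateral input)
τ_I dI/dt = −I + Sigm(C_EI·E + C_II·I + Q + lateral input)
```

with `Sigm(x) = 1/(1+e^{−a(x−θ)})`, `a = 1`, `θ = 4`.  *P* and *Q* set the
baseline drive of the two populations; every experiment manipulates
excitability through them.  Macrocolumns (10×10 minicolumns) share one
standard-normal noise stream; integration is Euler–Maruyama at dt = 2 ms.
Depending on the surround drive the coupled sheet is in a monostable
background state (P < −2.5), a bistable regime where background and
seizure states coexist (−2.5 < P < −1.1), or a monostable seizure state —
the spatial mechanism behind the two onset patterns and behind the
different surgical outcomes.  See `docs/methods.md` for the full account.

## A worked example

```python
import ictalsheet as ish

# where is the tissue dynamically? (deterministic classification)
for P in (-4.0, -1.5, 1.0):
    print(P, ish.classify_state(P).label)

# the high-amplitude-slow onset, full 150x150 sheet
res, m = ish.run_onset_demo("HAS", seed=1)
print("onset (ms):", m.onset_time["amplitude_deviation"])
print("dominant onset frequency (Hz):", m.onset_frequency)
print("onset amplitude (a.u.):", round(m.onset_amplitude, 2))
print("full recruitment after ramp end (ms):", m.full_recruitment_time)
```

prints

```
-4.0 background
-1.5 bistable
1.0 seizure
onset (ms): 2456.0
dominant onset frequency (Hz): 9.25
onset amplitude (a.u.): 1.7
full recruitment after ramp end (ms): 0.0
```

The surround at −1.5 is bistable, so the single ramped microdomain (its
ramp starts at t = 2 s) triggers a recruitment wave a few hundred
milliseconds after it crosses the seizure threshold; the whole sheet is
recruited before the ramp even completes, and the recruited territory
oscillates near 9 Hz at high amplitude.  Running the `"LAF"` preset
instead gives a ~1 a.u. onset at ~12–15 Hz that grows over seconds — the
two clinical onset morphologies from one model, distinguished only by the
excitability of the surrounding tissue.

Short narrative scripts for each capability live in `examples/`; a thin
command-line interface (`ictalsheet demo|scan|surgery|track|classify|simulate`)
wraps the same functions.

## Layout

```
src/ictalsheet/
  model_core.py     # unit model, parameters, state classification
  connectivity.py   # lateral operators, resections, microdomain layouts
  simulator.py      # Euler-Maruyama sheet integration, event schedules
  observables.py    # LFP/ECoG, onset detectors, onset phenotype
  experiments.py    # demos, scans, surgery, tracking
  cli.py            # command-line front end
docs/methods.md     # model, calibration, measurement definitions, limits
examples/           # one narrative script per capability
tests/              # pytest suite incl. the acceptance battery
```
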