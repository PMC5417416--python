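# Methods

## The model

Each cortical minicolumn (~50 µm across) is a Wilson–Cowan pair: the
fractional firing activities *E* and *I* of its excitatory and inhibitory
populations evolve as

    tau_E dE/dt = -E + Sigm(C_EE·E + C_IE·I + P + A_s·S(t) + lateral E input)
    tau_I dI/dt = -I + Sigm(C_EI·E + C_II·I + Q + lateral I input)

with the logistic response `Sigm(x) = 1/(1 + exp(-a(x - θ)))`, `a = 1`,
`θ = 4`.  *P* and *Q* are the baseline drives of the two populations and are
the excitability knobs of every experiment in this package.  A sheet is a
150×150 lattice of such units (macrocolumns are 10×10 blocks sharing one
subcortical noise stream S(t), drawn fresh from a standard normal each
step).  Lateral interactions are three sparse operators: local feed-forward
excitation (E→E) and inhibition (E→I) drawn with probability
`p0·exp(-d/decay)` up to a cutoff radius, and patchy remote excitation —
each column projects to a few distant clusters 1–3 mm away.  Rows of each
operator are rescaled so every column's lateral in-weight sums to a fixed
total; a homogeneous sheet is then exactly equivalent to one effective unit
with couplings `C_EE + w_EE_local + w_EE_remote` and `C_EI + w_EI_local`.

Integration is fixed-step Euler–Maruyama with dt = 2 ms.  By default the
noise enters inside the excitatory sigmoid argument (`A_s·scale·S`); an
additive diffusion variant (`E += drift·dt + (A_s·scale/τ_E)·√dt·ξ`) is
available through `NoiseModel(mode="additive")`.

## Default parameters and how they were fixed

The within-column couplings, time constants, the operating Q, the lateral
weight split and the noise scale are not independently meaningful — they
were *calibrated jointly* so that the sheet reproduces a specific set of
dynamical landmarks:

| target | value |
|---|---|
| deterministic bistable band of the surround drive | P ∈ (−2.5, −1.1) |
| monostable background / monostable seizure | P = −4 / P = 1 |
| rhythm of a large recruited territory (P = −1.5) | ≈ 9 Hz |
| rhythm of small strongly driven patches (P → 2) | ≈ 14 Hz |
| one-patch recruitment of the sheet at P = −1.5 | ≪ 1 s |
| background at P = −1.5 stable under noise | ≥ 30 s |

The shipped solution ("calibrated-v1"): `tau_E = 10 ms`, `tau_I = 15 ms`,
`C_EE = 45`, `C_IE = −60`, `C_EI = 37`, `C_II = −9`, `Q = −12.4`;
connectivity `local_radius = 4`, `decay = 2`, `p0 = 0.3`,
`w_EE_local = 11`, `w_EE_remote = 2` over 4 remote clusters,
`w_EI_local = 12`; `NoiseModel.scale = 0.4`.

Three structural facts about this parameter family are worth knowing:

1. **Bistability is a sheet-level property.**  A single unit at the
   operating Q is excitable below the fold at P ≈ −1.05 and oscillatory
   above it; it has no coexistence window.  Inside the band the seizure
   state is spatial: slow re-entrant waves sustained by the near-threshold
   lateral excitation.  The lower band edge (−2.5) is the propagation-
   failure point of these waves and is set by the lateral weights; the
   upper edge (−1.1) is the deterministic fold of the quiescent state and
   is set by Q.  A homogeneous sheet started quiescent stays quiescent
   everywhere in the band; an established spatially disordered oscillation
   persists.  State classification therefore integrates a real coupled
   sheet (60×60 reference), taking its seizure-side initial condition from
   a single noisy establishment run at P = 1 with a fixed seed; the
   classification integrations themselves are noise-free and the procedure
   is deterministic.
2. **The frequency split is a size/drive effect.**  A large coherent
   territory at P = −1.5 cycles at the slow re-ignition rate (~9 Hz);
   small, strongly driven patches escape most of the slow lateral drive
   they would receive inside a large domain and run near 14 Hz.
3. **The noise scale is a calibrated solver constant.**  With the raw
   standard-normal draw applied at unit amplitude each 2 ms step, the
   noise-smoothed sigmoid destroys the quiescent state at P = −1.5 in
   under a second for *every* parameter family that also has the band at
   (−2.5, −1.1) — the smoothed fold shifts down by roughly
   (κ−1)(ln C_EE + 1) ≈ 0.7 drive units.  The per-step amplitude is
   therefore a calibration constant (0.4; the transition to
   noise-dominated dynamics sits near 0.6).

## Observables

*LFP* of a column: `norm·(w_E·E + w_I·I + w_S·s)` with `w_E = 1`,
`w_I = −0.3`, `w_S = 0.1`, where `s` is the effective noise input the
column received.  *ECoG*: mean LFP over all active (non-resected) columns,
high-pass filtered at 1 Hz with a second-order zero-phase Butterworth.
The global constant `norm = 53.6` was fixed once so that the
low-amplitude-fast demo has onset amplitude ≈ 1 arbitrary unit; every
amplitude statement in the scans is a ratio and survives this choice.

*Onset detectors.*  Three detectors flag the first sustained excursion of a
running statistic beyond 3 baseline standard deviations: the rectified
100 ms ECoG envelope, the 200 ms running mean of the unfiltered signal (DC
shift), and the 100 ms smoothed |slope|.  All detector statistics use
trailing (causal) windows so they cannot anticipate an event, and each must
stay above threshold longer than its own autocorrelation time (100, 300 and
80 ms respectively) — on 12 s of pure background none of them fires.

*Onset frequency* is the lowest strong local Welch peak in the 8–45 Hz
band of the 2 s post-onset window (1 s segments, zero-padded).  Below 8 Hz
the spectrum carries the recruitment envelope and the beat-skipped
responses of tissue that cannot follow the seizure rhythm 1:1; spiky
waveforms also put harmonics above the fundamental, hence the
lowest-strong-peak rule rather than a bare argmax.

*Onset amplitude*: mean peak-to-trough range of the ECoG cycles in the 2 s
window after onset (cycles delimited by successive peaks).

*Recruitment*: a column counts as recruited when its E envelope (running
maximum over 150 ms, about 1.5 seizure cycles) exceeds the midpoint between
the surround background-equilibrium E and the seizure-cycle mean E; the
fraction is smoothed with a 50 ms majority filter.  Full recruitment is the
first time ≥ 99% of active columns are recruited, clocked from completion
of the first patch's ramp (recorded in provenance).

*Stimulation response*: the stimulated column's own LFP in the 100 ms
after pulse onset, smoothed with a 20 ms moving average; the maximum is the
response amplitude, averaged per 400 ms cycle over the 9 probe sites.

## The experiments

* **Onset demos** (`run_onset_demo`): the two canonical onset presets.  LAF: 15
  microdomains totalling 5% of columns, surround P = −2.5, patches ramped
  to P = 2 over 3 s, 50 ms activation gaps.  HAS: one microdomain, surround
  P = −1.5, ramp to P = 1.  Each run gets a 2 s quiet lead-in before the
  first ramp so the detectors have a clean baseline, and a 200 ms noisy
  burn-in before recording.
* **Parameter scan** (`run_parameter_scan`): onset amplitude and frequency
  over surround drive × percentage × patch count with several random
  layouts per cell, on a scaled 60×60 sheet; an equivalent scan over the
  inhibitory baseline drive Q is available (decreasing Q acts like
  increasing P).
* **Surgery** (`run_surgery_experiment`): matched monostable (−4) vs
  bistable (−1.5) runs with identical layout, connectivity and noise; a
  strip covering 20% of the lattice columns, centred on the first-activated
  microdomain, is removed by deleting all its edges and freezing its state.
* **Excitability tracking** (`run_excitability_tracking`): a staircase of
  the global drive (5 levels over [−4, −1.5], 4 s each) probed every 400 ms
  by successive 6 ms, +5-unit pulses at 9 grid sites; Pearson correlation
  between the staircase level and the per-cycle mean response.  Cycles at
  or after a probe-triggered global seizure are flagged and excluded.

## Problem sizes

The onset demos run on the full 150×150 sheet.  The scan, surgery and
tracking experiments default to a 60×60 sheet, and the classification
context is a 60×60 reference sheet; these sizes retain all qualitative
regimes (the re-entrant wavelength fits comfortably) while keeping a full
experiment battery in the minutes range on one CPU core.  A 30×30 sheet is
*too small* for the sustained seizure state at the default connectivity —
the remote-projection annulus (1–3 mm) barely fits and re-entry has no
room — which is why classification does not use it.

## Known limitations

* The low-amplitude-fast onset frequency is measured while the patches are
  still ramping; the printed ~14 Hz is reached only near the end of the
  window, so the 3-seed mean sits at the low end of the 14 ± 2 Hz range
  and individual seeds can fall below it.
* The frequency–size relation among *driven* patches is nearly flat (5×5
  to 40×40 all cycle within ~1 Hz of each other once noise-driven internal
  waves develop); the robust frequency split in this model is between
  driven patches and the recruited surround, not among patch sizes.
* The probe-response correlation in the tracking experiment is ~0.96–0.98,
  higher than the published 0.8246 — the model's responses are less noisy
  than the original's.
* In the monostable −4 surround, microdomains cannot recruit surrounding
  tissue at all (the pre-resection control in the surgery pair shows
  microdomain activity only); full recruitment of a monostable surround
  happens at −2.5 but not at −4.
* Onset amplitudes in the monostable scan slice are not far below the
  0.5-unit dichotomy line; the amplitude contrast between the monostable
  and bistable regimes is ~2–3×, smaller than in the original report.
* Seizure termination, slow timescales, high-frequency oscillations and
  conduction delays are out of scope.

## What the synthetic experiments do not show

All inputs here are declarative configurations; there is no clinical data
anywhere in the pipeline.  Passing tests show that the *mechanisms* —
surround-excitability-dependent onset patterns, sheet-level bistability,
resection outcomes, active probing — behave as described within this
idealized lattice.  They say nothing about parameter identifiability from
real recordings, about electrode physics (the ECoG here is a plain spatial
mean), or about tissues whose excitability varies in space and time.
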