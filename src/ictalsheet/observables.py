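"""LFP/ECoG synthesis and the seizure-onset phenotype.

Per-column local field potential: a weighted sum of the column's excitatory
activity, inhibitory activity and its (macrocolumn) noise input.  The
simulated ECoG electrode lying over the whole sheet is approximated by the
mean LFP over all active (non-resected) columns, high-pass filtered at 1 Hz
(second-order Butterworth, forward-backward, i.e. zero phase).

From the ECoG the onset phenotype is computed: onset time (three detector
families), onset amplitude in arbitrary units (mean cycle peak-to-trough
over a 2 s post-onset window), dominant post-onset frequency (Welch), the
recruitment-fraction curve and the full-recruitment latency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

__all__ = [
    "LfpWeights",
    "OnsetMetrics",
    "DEFAULT_LFP_NORM",
    "lfp",
    "mean_lfp",
    "ecog",
    "detect_onset",
    "onset_amplitude",
    "dominant_frequency",
    "onset_psd",
    "spectral_peak",
    "recruitment",
    "stimulation_response",
]

#: Global ECoG normalization constant, fixed once so the low-amplitude-fast
#: onset demo has onset amplitude ~1 arbitrary unit; every amplitude
#: comparison in the parameter scans is a ratio and survives this choice.
DEFAULT_LFP_NORM: float = 53.6


@dataclass(frozen=True)
class LfpWeights:
    """Weights of E, I and noise input in the per-column LFP."""

    w_E: float = 1.0
    w_I: float = -0.3
    w_S: float = 0.1
    norm: float = DEFAULT_LFP_NORM

    def __post_init__(self) -> None:
        if not np.isfinite([self.w_E, self.w_I, self.w_S, self.norm]).all():
            raise ValueError("LFP weights must be finite")


@dataclass
class OnsetMetrics:
    """Onset phenotype of one simulation."""

    onset_time: dict = field(default_factory=dict)  # ms per detector
    onset_amplitude: float | None = None            # arbitrary units
    onset_frequency: float | None = None            # Hz
    recruitment_curve: np.ndarray | None = None
    recruitment_t: np.ndarray | None = None
    full_recruitment_time: float | None = None      # ms, None = never
    provenance: dict = field(default_factory=dict)


def _noise_at_frames(result):
    """Per-column *effective* noise input (A_s x solver scale x draw),
    downsampled to the recorded frames."""
    idx = np.arange(result.stride - 1, result.noise.shape[0], result.stride)
    S = result.noise[idx]
    prov = result.provenance
    gain = (prov.get("model", {}).get("A_s", 1.0)
            * prov.get("noise", {}).get("scale", 1.0))
    return gain * S[:, result.macro_of_columns()]


def lfp(result, weights: LfpWeights = LfpWeights(), columns=None) -> np.ndarray:
    """Per-column LFP, (n_frames, n_selected)."""
    sl = slice(None) if columns is None else np.asarray(columns)
    S = _noise_at_frames(result)[:, sl]
    out = (weights.w_E * result.E[:, sl].astype(float)
           + weights.w_I * result.I[:, sl].astype(float)
           + weights.w_S * S)
    return weights.norm * out


def mean_lfp(result, weights: LfpWeights = LfpWeights()) -> np.ndarray:
    """Unfiltered mean LFP over active columns (the raw electrode signal)."""
    act = result.active_mask
    if not act.any():
        raise ValueError("no active columns")
    E = result.E[:, act].mean(axis=1, dtype=float)
    I = result.I[:, act].mean(axis=1, dtype=float)
    S = _noise_at_frames(result)[:, act].mean(axis=1)
    return weights.norm * (weights.w_E * E + weights.w_I * I + weights.w_S * S)


def highpass_1hz(x: np.ndarray, fs: float, cutoff: float = 1.0) -> np.ndarray:
    sos = sps.butter(2, cutoff, btype="highpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def ecog(result, weights: LfpWeights = LfpWeights()) -> np.ndarray:
    """Simulated single-channel ECoG: mean active-column LFP, 1 Hz high-pass."""
    return highpass_1hz(mean_lfp(result, weights), result.fs)


def _causal_mean(x: np.ndarray, fs: float, window_ms: float) -> np.ndarray:
    """Trailing moving average: sample t sees only x[t-w+1 .. t], so a
    detector statistic can never anticipate an event."""
    w = max(1, int(round(window_ms * fs / 1000.0)))
    return np.convolve(x, np.ones(w) / w, mode="full")[:len(x)]


def _envelope(x: np.ndarray, fs: float, window_ms: float = 100.0) -> np.ndarray:
    """Rectified trailing moving average."""
    return _causal_mean(np.abs(x), fs, window_ms)


def _moving_mean(x: np.ndarray, fs: float, window_ms: float) -> np.ndarray:
    w = max(1, int(round(window_ms * fs / 1000.0)))
    return np.convolve(x, np.ones(w) / w, mode="same")


def _first_sustained(above: np.ndarray, n_sustain: int) -> int | None:
    """Index of the first run of ``n_sustain`` consecutive True values."""
    if n_sustain <= 1:
        hits = np.flatnonzero(above)
        return int(hits[0]) if len(hits) else None
    conv = np.convolve(above.astype(int), np.ones(n_sustain, int),
                       mode="valid")
    hits = np.flatnonzero(conv == n_sustain)
    return int(hits[0]) if len(hits) else None


def detect_onset(ecog_signal: np.ndarray, fs: float, method: str,
                 baseline_window: float = 2000.0, t0: float = 0.0,
                 k: float = 3.0, unfiltered: np.ndarray | None = None,
                 sustain_ms: float | None = None) -> float | None:
    """Seizure onset time (ms) from the simulated ECoG, or None.

    All three detectors flag the first ``sustain_ms``-sustained excursion of
    a running statistic beyond ``k`` baseline standard deviations of its
    baseline mean:

    ``amplitude_deviation``
        rectified 100 ms moving-average envelope of the filtered ECoG;
    ``dc_shift``
        200 ms running mean of the *unfiltered* mean signal (the seizure
        state carries a standing shift in mean firing);
    ``steepness``
        100 ms moving average of |dx/dt| of the filtered ECoG.

    ``baseline_window`` (ms, >= 1000) must precede any scheduled event;
    ``t0`` is the time of the first recorded frame.  ``sustain_ms`` defaults
    per method (amplitude 100, dc 300, steepness 80 ms): a statistic must
    out-last its own autocorrelation time before it counts, which keeps the
    false-alarm rate on pure background negligible.
    """
    if baseline_window < 1000.0:
        raise ValueError("baseline window must be at least 1 s")
    nb = int(round(baseline_window * fs / 1000.0))
    if nb >= len(ecog_signal):
        raise ValueError("baseline window longer than the signal")
    if sustain_ms is None:
        sustain_ms = {"amplitude_deviation": 100.0, "dc_shift": 300.0,
                      "steepness": 80.0}.get(method, 100.0)
    n_sus = max(1, int(round(sustain_ms * fs / 1000.0)))

    if method == "amplitude_deviation":
        stat = _envelope(ecog_signal, fs)
        two_sided = False
    elif method == "dc_shift":
        x = ecog_signal if unfiltered is None else unfiltered
        stat = _causal_mean(x, fs, 200.0)
        two_sided = True
    elif method == "steepness":
        # pre-smooth so the white noise floor does not drown the slope
        smooth = _causal_mean(ecog_signal, fs, 30.0)
        stat = _causal_mean(np.abs(np.gradient(smooth)), fs, 100.0)
        two_sided = False
    else:
        raise ValueError(f"unknown onset detector {method!r}")
    mu, sd = stat[:nb].mean(), stat[:nb].std()
    dev = np.abs(stat - mu) if two_sided else stat - mu
    idx = _first_sustained(dev > k * max(sd, 1e-12), n_sus)
    if idx is None or idx < nb:
        return None
    return t0 + idx * 1000.0 / fs


def _window(sig: np.ndarray, fs: float, t0: float, start_ms: float,
            window_ms: float):
    i0 = int(round((start_ms - t0) * fs / 1000.0))
    i1 = i0 + int(round(window_ms * fs / 1000.0))
    i0 = max(i0, 0)
    clipped = i1 > len(sig)
    return sig[i0:min(i1, len(sig))], clipped


def onset_amplitude(ecog_signal: np.ndarray, fs: float, onset_time: float,
                    window_ms: float = 2000.0, t0: float = 0.0):
    """Mean cycle peak-to-trough range over the post-onset window (a.u.).

    Cycles are delimited by successive signal peaks; the amplitude of one
    cycle is the signal range between them.  Scale covariant: scaling the
    ECoG by c scales the result by c.  If the window extends beyond the
    signal it is shrunk (recorded in the returned provenance flag).
    """
    seg, clipped = _window(ecog_signal, fs, t0, onset_time, window_ms)
    if len(seg) < int(fs):
        return None, True
    f_dom = dominant_frequency(ecog_signal, fs, onset_time, window_ms, t0=t0)
    if f_dom is None:
        return float(np.ptp(seg)), clipped
    min_dist = max(1, int(0.6 * fs / f_dom))
    peaks, _ = sps.find_peaks(seg, distance=min_dist)
    if len(peaks) < 3:
        return float(np.ptp(seg)), clipped
    ranges = [np.ptp(seg[peaks[i]:peaks[i + 1] + 1])
              for i in range(len(peaks) - 1)]
    return float(np.mean(ranges)), clipped


def onset_psd(ecog_signal: np.ndarray, fs: float, onset_time: float,
              window_ms: float = 2000.0, t0: float = 0.0):
    """Welch PSD of the post-onset window (1 s segments, zero-padded), or
    None when the window holds less than a second of data.  Spectra from
    repeated runs at the same sampling rate share the frequency grid and
    can be averaged before peak extraction."""
    seg, _ = _window(ecog_signal, fs, t0, onset_time, window_ms)
    if len(seg) < int(fs):
        return None
    nper = int(fs)
    return sps.welch(seg - seg.mean(), fs=fs, nperseg=nper, nfft=4 * nper)


def spectral_peak(f: np.ndarray, p: np.ndarray, f_min: float = 8.0,
                  f_max: float = 45.0) -> float | None:
    """Onset-rhythm peak of a PSD: the lowest local maximum in the band
    carrying at least half the maximal peak power (harmonic-robust)."""
    band = (f >= f_min) & (f <= f_max)
    if not band.any() or p[band].max() <= 0:
        return None
    fb, pb = f[band], p[band]
    peaks, _ = sps.find_peaks(pb)
    if len(peaks):
        strong = peaks[pb[peaks] >= 0.5 * pb[peaks].max()]
        peak = int(strong[0])
    else:
        peak = int(np.argmax(pb))
    if pb[peak] < 2.0 * np.median(pb):
        return None
    return float(fb[peak])


def dominant_frequency(ecog_signal: np.ndarray, fs: float, onset_time: float,
                       window_ms: float = 2000.0, t0: float = 0.0,
                       f_min: float = 8.0) -> float | None:
    """Frequency (Hz) of the maximal Welch peak in the post-onset window.

    The search starts at ``f_min`` (default 8 Hz): onset patterns are
    characterised by their fast rhythmic component in the alpha/beta band,
    while the sub-8 Hz range carries the recruitment envelope and the
    beat-skipped responses of surrounding tissue rather than the onset
    rhythm itself.  1 s segments (<= 1 Hz resolution), zero-padded for peak
    interpolation; returns None when no peak rises above the broadband
    floor.
    """
    psd = onset_psd(ecog_signal, fs, onset_time, window_ms, t0)
    if psd is None:
        return None
    return spectral_peak(*psd, f_min=f_min)


def recruitment(result, seizure_threshold: float, clock_zero_ms: float = 0.0,
                envelope_ms: float = 150.0, smooth_ms: float = 50.0):
    """Recruited fraction of active columns over time and full-recruitment
    latency.

    A column counts as recruited at a frame when its E envelope (running
    maximum over ``envelope_ms``, which spans at least one seizure cycle)
    exceeds ``seizure_threshold`` (typically the midpoint between the
    background-equilibrium E and the seizure-cycle mean E of the surround
    parameters).  The per-column boolean is cleaned with a ``smooth_ms``
    majority filter.  ``full_recruitment_time`` is the first time with
    fraction >= 0.99, measured from ``clock_zero_ms`` (end of the first
    patch ramp in the onset experiments); None if never reached.
    """
    from scipy.ndimage import maximum_filter1d, uniform_filter1d

    act = result.active_mask
    E = result.E[:, act].astype(np.float32)
    w = max(1, int(round(envelope_ms * result.fs / 1000.0)))
    level = maximum_filter1d(E, w, axis=0, mode="nearest")
    rec = level > seizure_threshold
    sw = max(1, int(round(smooth_ms * result.fs / 1000.0)))
    if sw > 1:
        rec = uniform_filter1d(rec.astype(np.float32), sw, axis=0,
                               mode="nearest") > 0.5
    frac = rec.mean(axis=1)
    hits = np.flatnonzero((frac >= 0.99) & (result.t >= clock_zero_ms))
    full = float(result.t[hits[0]] - clock_zero_ms) if len(hits) else None
    return frac, result.t.copy(), full


def stimulation_response(result, sites, schedule,
                         weights: LfpWeights = LfpWeights(),
                         smooth_ms: float = 20.0, window_ms: float = 100.0,
                         period_ms: float = 400.0):
    """Per-cycle mean maximal stimulation response at the probed columns.

    For every pulse the stimulated column's own LFP in the
    ``window_ms`` window from pulse onset is smoothed with a ``smooth_ms``
    moving average and its maximum taken as the response amplitude.  Pulses
    are grouped into cycles of ``period_ms``; per cycle the mean and
    standard error over the sites are reported.

    Returns a dict with arrays ``cycle_t`` (cycle start, ms), ``mean``,
    ``sem`` and the full (n_cycles, n_sites) response matrix.
    """
    pulses = schedule.pulses()
    if not pulses:
        raise ValueError("schedule contains no pulses")
    site_list = [int(s) for s in sites]
    col_lfp = lfp(result, weights, columns=site_list)
    fs = result.fs
    t0 = result.t[0]
    n_cycles = int(max(p.t_start for p in pulses) // period_ms) + 1
    resp = np.full((n_cycles, len(site_list)), np.nan)
    last_end = {}
    for p in pulses:
        site = p.support[0]
        j = site_list.index(site)
        c = int(p.t_start // period_ms)
        if site in last_end and p.t_start < last_end[site]:
            raise ValueError("overlapping response windows at one site")
        last_end[site] = p.t_start + window_ms
        seg, _ = _window(col_lfp[:, j], fs, t0, p.t_start, window_ms)
        if len(seg) == 0:
            continue
        sm = _moving_mean(seg, fs, smooth_ms)
        resp[c, j] = sm.max()
    valid = ~np.all(np.isnan(resp), axis=1)
    resp = resp[valid]
    cyc = np.flatnonzero(valid) * period_ms
    mean = np.nanmean(resp, axis=1)
    sem = stats.sem(resp, axis=1, nan_policy="omit")
    return {"cycle_t": cyc, "mean": mean, "sem": np.asarray(sem),
            "responses": resp}


def export_ecog_csv(result, path: str,
                    weights: LfpWeights = LfpWeights()) -> None:
    """Write the simulated ECoG channel as a two-column CSV (t_ms, ecog)."""
    sig = ecog(result, weights)
    arr = np.column_stack([result.t, sig])
    np.savetxt(path, arr, delimiter=",", header="t_ms,ecog", comments="")
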