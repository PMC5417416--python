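"""End-to-end experiment pipelines: onset demos, parameter scans, in-silico
surgery and active excitability tracking.

Each pipeline derives its sub-seeds (connectivity, microdomain layout,
noise) from one master seed, builds the sheet, runs the schedule and
reduces the result to onset metrics.  The named onset presets (the parameter rows of the two
canonical onset patterns and the surgery scenarios) are available
verbatim via :data:`ONSET_PRESETS`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model_core import (ColumnParameters, SheetGeometry, ParameterField,
                         SheetState, DEFAULT_PARAMS, DEFAULT_Q,
                         background_equilibrium, seizure_cycle_stats)
from .connectivity import (ConnectivityConfig, ConnectivityMatrices,
                           ResectionMask, build_connectivity, apply_resection,
                           place_microdomains)
from .simulator import (NoiseModel, Event, EventSchedule, simulate,
                        make_onset_schedule, make_stimulation_schedule,
                        default_stimulation_sites)
from . import observables as obs

__all__ = [
    "ONSET_PRESETS",
    "ExperimentConfig",
    "derive_seeds",
    "run_onset_demo",
    "run_parameter_scan",
    "run_surgery_experiment",
    "run_excitability_tracking",
    "compute_onset_metrics",
]

#: Named parameter rows (surround drive, patch ramp target, patch count,
#: percentage of hyperactive minicolumns).  The surgery scenarios ship two
#: low-amplitude variants: a deeply monostable surround (-4, the default
#: monostable-vs-bistable contrast) and a moderately monostable one (-2.5).
ONSET_PRESETS = {
    "LAF": dict(P_surround=-2.5, P_patch_end=2.0, n_patches=15, percent=5.0),
    "HAS": dict(P_surround=-1.5, P_patch_end=1.0, n_patches=1, percent=5.0),
    "surgery_LAF": dict(P_surround=-4.0, P_patch_end=1.0, n_patches=15,
                        percent=5.0),
    "surgery_LAF_moderate": dict(P_surround=-2.5, P_patch_end=1.0,
                                 n_patches=15, percent=5.0),
    "surgery_HAS": dict(P_surround=-1.5, P_patch_end=1.0, n_patches=15,
                        percent=5.0),
}

RAMP_MS = 3000.0
GAP_MS = 50.0
LEAD_IN_MS = 2000.0  # quiet baseline before the first ramp starts


@dataclass
class ExperimentConfig:
    """Declarative description of one experiment run."""

    kind: str = "onset_demo"
    preset: str = "LAF"
    geometry: SheetGeometry = field(default_factory=SheetGeometry)
    params: ColumnParameters = field(default_factory=lambda: DEFAULT_PARAMS)
    Q: float = DEFAULT_Q
    n_random_configs: int = 10
    seed: int = 0
    duration: float | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "geometry" in d and isinstance(d["geometry"], dict):
            d["geometry"] = SheetGeometry(**d["geometry"])
        if "params" in d and isinstance(d["params"], dict):
            d["params"] = ColumnParameters(**d["params"])
        return cls(**d)


def derive_seeds(master: int, n: int = 3):
    """Independent 31-bit sub-seeds (connectivity, layout, noise, ...)."""
    ss = np.random.SeedSequence(master)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


def _lateral_gains(conn_cfg: ConnectivityConfig):
    return (conn_cfg.w_EE_local + conn_cfg.w_EE_remote, conn_cfg.w_EI_local)


def _recruitment_threshold(P_surround, P_patch_end, Q, params, conn_cfg):
    """Midpoint between the surround background-equilibrium E and the
    seizure-cycle mean E (taken at the monostable patch drive)."""
    gE, gI = _lateral_gains(conn_cfg)
    e_bg, _ = background_equilibrium(P_surround, Q, params,
                                     lateral_E_gain=gE, lateral_I_gain=gI)
    sz = seizure_cycle_stats(P_patch_end, Q, params,
                             lateral_E_gain=gE, lateral_I_gain=gI)
    return 0.5 * (e_bg + sz["mean"])


def compute_onset_metrics(result, P_surround, P_patch_end, Q=DEFAULT_Q,
                          params=DEFAULT_PARAMS,
                          conn_cfg=ConnectivityConfig(),
                          weights=obs.LfpWeights(),
                          clock_zero_ms=LEAD_IN_MS + RAMP_MS,
                          baseline_window=LEAD_IN_MS) -> obs.OnsetMetrics:
    """Full onset phenotype of an onset-style simulation."""
    raw = obs.mean_lfp(result, weights)
    sig = obs.highpass_1hz(raw, result.fs)
    t0 = float(result.t[0])
    m = obs.OnsetMetrics()
    for method in ("amplitude_deviation", "dc_shift", "steepness"):
        m.onset_time[method] = obs.detect_onset(
            sig, result.fs, method, baseline_window=baseline_window,
            t0=t0, unfiltered=raw)
    onset = next((m.onset_time[k] for k in
                  ("amplitude_deviation", "dc_shift", "steepness")
                  if m.onset_time[k] is not None), None)
    if onset is not None:
        m.onset_amplitude, clipped = obs.onset_amplitude(
            sig, result.fs, onset, t0=t0)
        m.onset_frequency = obs.dominant_frequency(
            sig, result.fs, onset, t0=t0)
        m.provenance["amplitude_window_clipped"] = clipped
    thr = _recruitment_threshold(P_surround, P_patch_end, Q, params, conn_cfg)
    curve, t, full = obs.recruitment(result, thr, clock_zero_ms=clock_zero_ms)
    m.recruitment_curve, m.recruitment_t = curve, t
    m.full_recruitment_time = full
    m.provenance.update({
        "seizure_threshold": thr,
        "clock_zero_ms": clock_zero_ms,
        "P_surround": P_surround, "P_patch_end": P_patch_end, "Q": Q,
    })
    return m


def _onset_run(geometry, params, Q, preset, seed, duration, conn=None,
               conn_cfg=None, stride=1, resection_mask=None,
               drop_masked_patches=False):
    """Shared machinery of the onset-style experiments."""
    conn_seed, layout_seed, noise_seed = derive_seeds(seed)
    conn_cfg = conn_cfg or ConnectivityConfig(seed=conn_seed)
    if conn is None:
        conn = build_connectivity(geometry, conn_cfg)
    patches = place_microdomains(geometry, preset["n_patches"],
                                 preset["percent"], seed=layout_seed)
    sched = make_onset_schedule(patches, preset["P_patch_end"], RAMP_MS,
                                GAP_MS, preset["P_surround"])
    # shift every event past the quiet lead-in
    events = [dataclasses.replace(e, t_start=e.t_start + LEAD_IN_MS)
              for e in sched.events]
    if resection_mask is not None and drop_masked_patches:
        masked = set(int(i) for i in resection_mask.indices)
        kept = []
        for e in events:
            if e.support is None:
                kept.append(e)
                continue
            sup = tuple(i for i in e.support if i not in masked)
            if sup:
                kept.append(dataclasses.replace(e, support=sup))
        events = kept
    sched = EventSchedule(events)
    res = simulate(params, conn, sched, duration, NoiseModel(seed=noise_seed),
                   geometry=geometry,
                   P=ParameterField.uniform(geometry, preset["P_surround"]),
                   Q=ParameterField.uniform(geometry, Q, name="Q"),
                   stride=stride, resection_mask=resection_mask,
                   burn_in_ms=200.0)
    res.provenance["patches"] = [len(p) for p in patches]
    res.provenance["master_seed"] = seed
    return res, patches, conn


def run_onset_demo(preset: str = "LAF", seed: int = 0,
                   geometry: SheetGeometry | None = None,
                   params: ColumnParameters = DEFAULT_PARAMS,
                   Q: float = DEFAULT_Q, duration: float | None = None,
                   stride: int = 1, conn: ConnectivityMatrices | None = None,
                   render_to: str | None = None):
    """Simulate one named onset preset and compute its metrics.

    LAF: 15 microdomains (5% of columns) ramped to a strongly monostable
    seizure drive inside a monostable background surround -- slow coalescence
    and low-amplitude fast ECoG onset.  HAS: one microdomain ramped inside a
    bistable surround -- a recruitment wavefront and a high-amplitude slower
    onset.
    """
    if preset not in ONSET_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; have {list(ONSET_PRESETS)}")
    row = ONSET_PRESETS[preset]
    geometry = geometry or SheetGeometry()
    if duration is None:
        duration = 9000.0 if row["n_patches"] > 1 else 7000.0
    res, patches, conn = _onset_run(geometry, params, Q, row, seed, duration,
                                    conn=conn, stride=stride)
    metrics = compute_onset_metrics(
        res, row["P_surround"], row["P_patch_end"], Q, params,
        clock_zero_ms=LEAD_IN_MS + RAMP_MS)
    if render_to:
        _render_demo(res, metrics, preset, render_to)
    return res, metrics


def run_parameter_scan(P_grid=None, Q_grid=None, percent_grid=(2.0, 5.0, 10.0),
                       n_patches_grid=(1, 5, 15), n_random_configs: int = 3,
                       geometry: SheetGeometry | None = None,
                       params: ColumnParameters = DEFAULT_PARAMS,
                       seed: int = 0, duration: float = 8000.0,
                       stride: int = 2, P_patch_end: float = 1.0):
    """Mean onset amplitude/frequency over a (excitability, percent,
    n_patches) grid with random microdomain layouts.

    Excitability is scanned through the surround P by default
    (``P_grid``); passing ``Q_grid`` instead scans the inhibitory baseline
    drive at fixed ``P_surround = -2.5`` (decreasing Q has the same effect
    as increasing P).  Returns a pandas DataFrame, one row per cell and
    layout; failed cells are recorded with NaN metrics.
    """
    import pandas as pd

    if P_grid is not None and Q_grid is not None:
        raise ValueError("scan either P or Q, not both")
    scan_q = Q_grid is not None
    axis = np.asarray(Q_grid if scan_q else
                      (P_grid if P_grid is not None
                       else [-4.0, -3.0, -2.5, -2.0, -1.5]), dtype=float)
    geometry = geometry or SheetGeometry(n_rows=60, n_cols=60)
    rows = []
    for x in axis:
        P_surround = -2.5 if scan_q else float(x)
        Qv = float(x) if scan_q else DEFAULT_Q
        for pct in percent_grid:
            for npat in n_patches_grid:
                for cfg_i in range(n_random_configs):
                    cell_seed = derive_seeds(seed, 6)[3] + hash(
                        (round(float(x), 6), pct, npat, cfg_i)) % (2 ** 20)
                    row = dict(P_surround=P_surround, P_patch_end=P_patch_end,
                               n_patches=int(npat), percent=float(pct))
                    try:
                        res, _, _ = _onset_run(geometry, params, Qv, row,
                                               cell_seed % (2 ** 31),
                                               duration, stride=stride)
                        m = compute_onset_metrics(
                            res, P_surround, P_patch_end, Qv, params)
                        rows.append({
                            "axis_value": float(x), "axis": "Q" if scan_q
                            else "P", "percent": pct, "n_patches": npat,
                            "config": cfg_i,
                            "onset_amplitude": m.onset_amplitude,
                            "onset_frequency": m.onset_frequency,
                            "full_recruitment_time": m.full_recruitment_time,
                        })
                    except Exception as err:  # record, continue scanning
                        rows.append({
                            "axis_value": float(x), "axis": "Q" if scan_q
                            else "P", "percent": pct, "n_patches": npat,
                            "config": cfg_i, "onset_amplitude": np.nan,
                            "onset_frequency": np.nan,
                            "full_recruitment_time": np.nan,
                            "error": str(err)})
    return pd.DataFrame(rows)


def run_surgery_experiment(seed: int = 0,
                           geometry: SheetGeometry | None = None,
                           surround_pair=(-4.0, -1.5),
                           n_patches: int = 15, percent: float = 5.0,
                           params: ColumnParameters = DEFAULT_PARAMS,
                           Q: float = DEFAULT_Q,
                           duration: float = 12000.0, stride: int = 2):
    """Four matched runs: (LAF-like, HAS-like) x (pre, post resection).

    The two scenarios share the identical microdomain layout, connectivity
    and noise; only the surround excitability differs.  The resected strip
    (all rows x 20% of lattice columns) is placed over the first-activated
    microdomain -- the area where the onset starts -- and must contain it
    entirely.
    """
    geometry = geometry or SheetGeometry(n_rows=60, n_cols=60)
    conn_seed, layout_seed, _ = derive_seeds(seed)
    conn_cfg = ConnectivityConfig(seed=conn_seed)
    conn = build_connectivity(geometry, conn_cfg)
    patches = place_microdomains(geometry, n_patches, percent,
                                 seed=layout_seed)
    width = max(1, int(round(geometry.n_cols * 30.0 / 150.0)))
    _, cols0 = geometry.rc(patches[0])
    center = int(round(np.mean(cols0)))
    start = int(np.clip(center - width // 2, 0, geometry.n_cols - width))
    mask = ResectionMask.strip(geometry, start, width)
    in_strip = np.isin(patches[0], mask.indices)
    if not in_strip.all():
        raise ValueError("resection strip does not cover the onset patch")
    conn_post = apply_resection(conn, mask)

    out = {}
    for label, P_surround in zip(("monostable", "bistable"), surround_pair):
        row = dict(P_surround=float(P_surround), P_patch_end=1.0,
                   n_patches=n_patches, percent=percent)
        for phase in ("pre", "post"):
            res, _, _ = _onset_run(
                geometry, params, Q, row, seed, duration,
                conn=conn if phase == "pre" else conn_post,
                conn_cfg=conn_cfg, stride=stride,
                resection_mask=None if phase == "pre" else mask,
                drop_masked_patches=(phase == "post"))
            m = compute_onset_metrics(res, float(P_surround), 1.0, Q, params)
            out[(label, phase)] = m
    out["mask"] = mask
    out["patches"] = patches
    return out


def staircase_schedule(levels, level_ms: float) -> list:
    """Whole-sheet P 'set' events forming a staircase."""
    return [Event("set", "P", None, t_start=i * level_ms, value=float(v))
            for i, v in enumerate(levels)]


def scheduled_P(levels, level_ms, t) -> float:
    i = min(int(t // level_ms), len(levels) - 1)
    return float(levels[i])


def run_excitability_tracking(seed: int = 0,
                              geometry: SheetGeometry | None = None,
                              levels=(-4.0, -3.375, -2.75, -2.125, -1.5),
                              level_ms: float = 4000.0,
                              params: ColumnParameters = DEFAULT_PARAMS,
                              Q: float = DEFAULT_Q, stride: int = 1,
                              pulse_amplitude: float = 5.0):
    """Track a global excitability staircase with 9-site active probing.

    Every 400 ms the 9 probe columns receive successive 6 ms, +5 P-unit
    pulses; per cycle the mean maximal smoothed LFP response over sites is
    computed and correlated (Pearson) with the scheduled P level.  Cycles
    after a probe-triggered global seizure are flagged and excluded.
    """
    geometry = geometry or SheetGeometry(n_rows=60, n_cols=60)
    conn_seed, _, noise_seed = derive_seeds(seed)
    conn = build_connectivity(geometry, ConnectivityConfig(seed=conn_seed))
    total_ms = level_ms * len(levels)
    sites = default_stimulation_sites(geometry)
    sched = EventSchedule(staircase_schedule(levels, level_ms))
    stim = make_stimulation_schedule(sites, total_ms,
                                     amplitude=pulse_amplitude)
    for e in stim.events:
        sched.add(e)
    res = simulate(params, conn, sched, total_ms, NoiseModel(seed=noise_seed),
                   geometry=geometry,
                   P=ParameterField.uniform(geometry, levels[0]),
                   Q=ParameterField.uniform(geometry, Q, name="Q"),
                   stride=stride, burn_in_ms=200.0)
    resp = obs.stimulation_response(res, sites, stim)
    P_at_cycle = np.array([scheduled_P(levels, level_ms, t)
                           for t in resp["cycle_t"]])
    # guard: drop cycles at/after a probe-triggered global transition
    thr = _recruitment_threshold(max(levels), 1.0, Q, params,
                                 ConnectivityConfig(seed=conn_seed))
    frac, t_frac, _ = obs.recruitment(res, thr)
    seizing = frac > 0.5
    if seizing.any():
        t_seiz = t_frac[np.argmax(seizing)]
        ok = resp["cycle_t"] + 400.0 <= t_seiz
    else:
        ok = np.ones(len(P_at_cycle), dtype=bool)
    r, p = (np.nan, np.nan)
    if np.std(P_at_cycle[ok]) > 0 and ok.sum() > 2:
        r, p = stats.pearsonr(P_at_cycle[ok], resp["mean"][ok])
    return {
        "result": res, "response": resp, "P_at_cycle": P_at_cycle,
        "pearson_r": float(r), "pearson_p": float(p),
        "cycles_used": int(ok.sum()), "seizure_triggered": bool(seizing.any()),
        "sites": sites, "levels": list(levels),
    }


def _render_demo(res, metrics, preset, path):  # pragma: no cover - plotting
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sig = obs.ecog(res)
    t_s = res.t / 1000.0
    fig = plt.figure(figsize=(10, 6))
    ax = fig.add_subplot(2, 1, 1)
    ax.plot(t_s, sig, lw=0.5, color="k")
    onset = metrics.onset_time.get("amplitude_deviation")
    if onset is not None:
        ax.axvline(onset / 1000.0, color="r", lw=1)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("ECoG (a.u.)")
    ax.set_title(f"{preset} onset demo")
    n_snap = 4
    for i in range(n_snap):
        axi = fig.add_subplot(2, n_snap, n_snap + 1 + i)
        fi = int(len(res.t) * (i + 1) / (n_snap + 1))
        axi.imshow(res.E[fi].reshape(res.geometry.n_rows,
                                     res.geometry.n_cols),
                   vmin=0, vmax=1, cmap="hot")
        axi.set_title(f"t = {res.t[fi]/1000.0:.1f} s", fontsize=8)
        axi.set_xticks([]), axi.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
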