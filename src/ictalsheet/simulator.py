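"""Stochastic integration of the full sheet under time-varying drives.

The sheet is advanced with a fixed-step Euler-Maruyama scheme (default
dt = 2 ms).  Subcortical noise is shared per macrocolumn: each 10x10 block
of minicolumns receives the same standard-normal stream.  Two noise
couplings are provided:

* ``in_drift`` (default): the draw S(t) enters the sigmoid argument of the
  excitatory drift as ``A_s * S``, one fresh draw per macrocolumn per step.
  The sigmoid bounds the noise influence, so the background state shows
  small fluctuations while the seizure oscillation is orders of magnitude
  larger.
* ``additive``: S acts as a diffusion increment on E directly,
  ``E += drift*dt + (A_s/tau_E) * sqrt(dt) * xi``.

Time-varying parameter fields (microdomain ramps, stimulation pulses,
global excitability drifts) are described by an :class:`EventSchedule` and
applied to the P/Q fields before every step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .model_core import (ColumnParameters, SheetGeometry, SheetState,
                         ParameterField, DEFAULT_PARAMS, DEFAULT_Q,
                         background_equilibrium)

__all__ = [
    "NoiseModel",
    "Event",
    "EventSchedule",
    "SimulationResult",
    "simulate",
    "run_with_halved_step",
    "make_onset_schedule",
    "make_stimulation_schedule",
    "save_result",
    "load_result",
]


@dataclass(frozen=True)
class NoiseModel:
    """Macrocolumn-shared standard-normal noise.

    ``mode`` selects the coupling (see module docstring).  Streams are drawn
    from one counter-based (Philox) generator keyed by ``seed``; resections
    never remove streams, so masking columns does not shift the noise seen
    by the rest of the sheet.

    ``scale`` is the per-step amplitude with which the standard-normal draw
    enters the integrator (the recorded stream stays standard normal).  The
    default is calibrated so that the bistable background survives on the
    multi-second timescale of the experiments while the seizure oscillation
    dwarfs the background ECoG fluctuation; the transition to
    noise-dominated dynamics sits near scale ~0.6.
    """

    seed: int = 0
    mode: str = "in_drift"
    scale: float = 0.4

    def __post_init__(self) -> None:
        if self.mode not in ("in_drift", "additive"):
            raise ValueError("mode must be 'in_drift' or 'additive'")
        if self.scale < 0:
            raise ValueError("noise scale must be non-negative")

    def draw(self, n_steps: int, n_macro: int) -> np.ndarray:
        rng = np.random.default_rng(np.random.Philox(key=self.seed))
        return rng.standard_normal((n_steps, n_macro))


@dataclass(frozen=True)
class Event:
    """One scheduled modification of a parameter field.

    kind
        ``"set"``   -- assign ``value`` at ``t_start`` (later sets override),
        ``"ramp"``  -- linear from ``value`` to ``end_value`` over
        ``duration`` ms, holding ``end_value`` afterwards,
        ``"pulse"`` -- add ``value`` during [t_start, t_start + duration).
    support
        column indices (None = whole sheet).
    """

    kind: str
    field_name: str = "P"
    support: tuple | None = None
    t_start: float = 0.0
    duration: float = 0.0
    value: float = 0.0
    end_value: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("set", "ramp", "pulse"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.field_name not in ("P", "Q"):
            raise ValueError("events target the P or Q field")
        if self.kind in ("ramp", "pulse") and self.duration <= 0:
            raise ValueError(f"{self.kind} events need a positive duration")
        if self.support is not None:
            object.__setattr__(self, "support",
                               tuple(int(i) for i in self.support))


@dataclass
class EventSchedule:
    """Ordered list of events; order breaks ties at equal start times."""

    events: list = field(default_factory=list)

    def add(self, event: Event) -> "EventSchedule":
        self.events.append(event)
        return self

    def pulses(self):
        return [e for e in self.events if e.kind == "pulse"]

    def end_time(self) -> float:
        if not self.events:
            return 0.0
        return max(e.t_start + e.duration for e in self.events)

    def to_dict(self) -> dict:
        out = []
        for e in self.events:
            d = asdict(e)
            d["support"] = None if e.support is None else list(e.support)
            out.append(d)
        return {"events": out}


@dataclass
class SimulationResult:
    """Recorded trajectories plus everything needed to re-run bit-identically.

    ``E``/``I`` are (n_frames, n_columns) float32 arrays at times ``t`` (ms,
    downsampled by ``stride``); ``noise`` is the full-rate
    (n_steps, n_macro) realized stream.  ``active_mask`` is False on
    resected columns.
    """

    t: np.ndarray
    E: np.ndarray
    I: np.ndarray
    noise: np.ndarray
    dt: float
    stride: int
    geometry: SheetGeometry
    active_mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def fs(self) -> float:
        """Sampling rate of the recorded frames, Hz."""
        return 1000.0 / (self.dt * self.stride)

    def macro_of_columns(self) -> np.ndarray:
        return self.geometry.macro_index()


def _apply_schedule_step(schedule, P, Q, base_P, base_Q, t, dt, active):
    """Mutate the P/Q work arrays to their value for the step at time t."""
    fields = {"P": (P, base_P), "Q": (Q, base_Q)}
    for e in schedule.events:
        work, base = fields[e.field_name]
        sup = slice(None) if e.support is None else list(e.support)
        if e.kind == "set":
            if t >= e.t_start:
                work[sup] = e.value
        elif e.kind == "ramp":
            if t >= e.t_start:
                frac = min(1.0, (t - e.t_start) / e.duration)
                work[sup] = e.value + frac * (e.end_value - e.value)
        elif e.kind == "pulse":
            if e.t_start <= t < e.t_start + e.duration:
                work[sup] = work[sup] + e.value


def simulate(model: ColumnParameters, conn, schedule: EventSchedule,
             duration: float, noise: NoiseModel, dt: float = 2.0,
             geometry: SheetGeometry | None = None,
             P: ParameterField | None = None,
             Q: ParameterField | None = None,
             init: SheetState | None = None,
             stride: int | None = None,
             resection_mask=None,
             burn_in_ms: float = 0.0) -> SimulationResult:
    """Integrate the sheet for ``duration`` ms; see module docstring.

    ``P``/``Q`` give the baseline fields (defaults: P = -2.5 everywhere and
    the operating Q).  ``init`` defaults to the background equilibrium of
    the mean baseline drive.  With ``burn_in_ms`` > 0 the sheet is first run
    for that long with noise but without schedule events (negative times,
    not recorded).  Resected columns are frozen at their initial state and,
    because the resected operators carry no edges for them, excluded from
    all lateral sums.
    """
    geometry = geometry or conn.geometry
    n = geometry.n_columns
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    n_steps = int(round(duration / dt))
    if abs(n_steps * dt - duration) > 1e-9:
        raise ValueError("duration must be a multiple of dt")
    if stride is None:
        stride = 1 if duration <= 20000.0 else 5
    if n_steps % stride:
        raise ValueError("stride must divide the number of steps")

    base_P = (P.values.copy() if P is not None
              else np.full(n, -2.5))
    base_Q = (Q.values.copy() if Q is not None
              else np.full(n, DEFAULT_Q))

    active = np.ones(n, dtype=bool)
    if resection_mask is not None:
        active[resection_mask.indices] = False
        for e in schedule.events:
            if e.support is not None and \
                    not active[np.asarray(e.support)].all():
                raise ValueError(
                    f"schedule event targets resected columns: {e}")

    if init is None:
        E0, I0 = background_equilibrium(float(np.mean(base_P)),
                                        float(np.mean(base_Q)), model)
        Ev = np.full(n, E0)
        Iv = np.full(n, I0)
    else:
        Ev = np.array(init.E, dtype=float).copy()
        Iv = np.array(init.I, dtype=float).copy()

    W_ee, W_ei, W_er = conn.matrices()
    macro = geometry.macro_index()
    n_macro = int(macro.max()) + 1
    n_burn = int(round(burn_in_ms / dt))
    S = noise.draw(n_burn + n_steps, n_macro)

    n_frames = n_steps // stride
    recE = np.empty((n_frames, n), dtype=np.float32)
    recI = np.empty((n_frames, n), dtype=np.float32)
    rec_t = np.empty(n_frames)

    p = model
    inv_tE, inv_tI = dt / p.tau_E, dt / p.tau_I
    drift_scale = p.A_s * noise.scale
    add_scale = p.A_s * noise.scale / p.tau_E * np.sqrt(dt)
    Pw = base_P.copy()
    Qw = base_Q.copy()
    frozenE = Ev[~active].copy()
    frozenI = Iv[~active].copy()
    frame = 0

    for k in range(n_burn + n_steps):
        t = (k - n_burn) * dt
        if k >= n_burn:
            Pw[:] = base_P
            Qw[:] = base_Q
            _apply_schedule_step(schedule, Pw, Qw, base_P, base_Q, t, dt,
                                 active)
        s_cols = S[k][macro]
        lat_E = W_ee.dot(Ev) + W_er.dot(Ev)
        lat_I = W_ei.dot(Ev)
        arg_E = p.C_EE * Ev + p.C_IE * Iv + Pw + lat_E
        if noise.mode == "in_drift":
            arg_E = arg_E + drift_scale * s_cols
        arg_I = p.C_EI * Ev + p.C_II * Iv + Qw
        Ev = Ev + inv_tE * (-Ev + 1.0 / (1.0 + np.exp(-p.a * (arg_E - p.theta))))
        Iv = Iv + inv_tI * (-Iv + 1.0 / (1.0 + np.exp(-p.a * (arg_I - p.theta))))
        if noise.mode == "additive":
            Ev = Ev + add_scale * s_cols
        if not active.all():
            Ev[~active] = frozenE
            Iv[~active] = frozenI
        if k >= n_burn and (k - n_burn) % stride == stride - 1:
            recE[frame] = Ev
            recI[frame] = Iv
            rec_t[frame] = t + dt
            frame += 1
        if k % 200 == 0 and not np.isfinite(Ev).all():
            raise FloatingPointError(
                f"non-finite state at step {k} (t = {t:.1f} ms)")

    prov = {
        "model": model.to_dict(),
        "noise": {"seed": noise.seed, "mode": noise.mode,
                  "scale": noise.scale},
        "schedule": schedule.to_dict(),
        "dt": dt, "stride": stride, "duration": duration,
        "burn_in_ms": burn_in_ms,
        "geometry": asdict(geometry),
        "connectivity": conn.provenance,
        "base_P_mean": float(np.mean(base_P)),
        "base_Q_mean": float(np.mean(base_Q)),
    }
    return SimulationResult(t=rec_t, E=recE, I=recI,
                            noise=S[n_burn:], dt=dt, stride=stride,
                            geometry=geometry, active_mask=active,
                            provenance=prov)


def run_with_halved_step(model, conn, schedule, duration, noise,
                         **kw) -> SimulationResult:
    """Validation helper: the same run at dt = 1 ms."""
    kw.pop("dt", None)
    return simulate(model, conn, schedule, duration, noise, dt=1.0, **kw)


def make_onset_schedule(patches, P_patch_end: float, ramp_ms: float = 3000.0,
                        gap_ms: float = 50.0, P_surround: float = -2.5,
                        ) -> EventSchedule:
    """Microdomain activation protocol.

    Sets P to ``P_surround`` on the whole sheet at t = 0, then ramps each
    patch linearly from ``P_surround`` to ``P_patch_end`` over ``ramp_ms``,
    with patch k starting at ``k * gap_ms`` (staggered activation).
    """
    if len(patches) > 1:
        flat = np.concatenate([np.asarray(p) for p in patches])
        if len(np.unique(flat)) != len(flat):
            raise ValueError("patches must be disjoint")
    sched = EventSchedule()
    sched.add(Event("set", "P", None, 0.0, 0.0, P_surround))
    for k, patch in enumerate(patches):
        sched.add(Event("ramp", "P", tuple(int(i) for i in np.asarray(patch)),
                        t_start=k * gap_ms, duration=ramp_ms,
                        value=P_surround, end_value=P_patch_end))
    return sched


def default_stimulation_sites(geometry: SheetGeometry):
    """9 probe columns on a 3x3 grid; positions {25, 75, 125} on the full
    150-column sheet, scaled proportionally for other sizes."""
    rr = [int(round(geometry.n_rows * f / 150.0)) for f in (25, 75, 125)]
    cc = [int(round(geometry.n_cols * f / 150.0)) for f in (25, 75, 125)]
    return [int(r * geometry.n_cols + c) for r in rr for c in cc]


def make_stimulation_schedule(sites, total_ms: float, amplitude: float = 5.0,
                              pulse_ms: float = 6.0,
                              inter_site_gap_ms: float = 6.0,
                              period_ms: float = 400.0) -> EventSchedule:
    """Successive single-column P pulses, repeated every ``period_ms``.

    Within each cycle the sites are pulsed one after another (pulse onsets
    ``pulse_ms + inter_site_gap_ms`` apart), so only one site is stimulated
    at any time.
    """
    if total_ms < period_ms:
        raise ValueError("total_ms must cover at least one cycle")
    n_sites = len(sites)
    slot = pulse_ms + inter_site_gap_ms
    if n_sites * slot - inter_site_gap_ms > period_ms:
        raise ValueError("pulses would overlap the next cycle")
    sched = EventSchedule()
    n_cycles = int(total_ms // period_ms)
    for c in range(n_cycles):
        for j, site in enumerate(sites):
            sched.add(Event("pulse", "P", (int(site),),
                            t_start=c * period_ms + j * slot,
                            duration=pulse_ms, value=amplitude))
    return sched


# ---------------------------------------------------------------------------
# persistence

def save_result(result: SimulationResult, path: str) -> None:
    """Persist a result to HDF5 (datasets /t /E /I /noise /mask)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("t", data=result.t)
        f.create_dataset("E", data=result.E, compression="gzip", shuffle=True)
        f.create_dataset("I", data=result.I, compression="gzip", shuffle=True)
        f.create_dataset("noise", data=result.noise, compression="gzip")
        f.create_dataset("mask", data=result.active_mask)
        f.attrs["dt"] = result.dt
        f.attrs["stride"] = result.stride
        f.attrs["geometry"] = json.dumps(asdict(result.geometry))
        f.attrs["provenance"] = json.dumps(result.provenance)


def load_result(path: str) -> SimulationResult:
    import h5py

    with h5py.File(path, "r") as f:
        geom = SheetGeometry(**json.loads(f.attrs["geometry"]))
        return SimulationResult(
            t=f["t"][:], E=f["E"][:], I=f["I"][:], noise=f["noise"][:],
            dt=float(f.attrs["dt"]), stride=int(f.attrs["stride"]),
            geometry=geom, active_mask=f["mask"][:].astype(bool),
            provenance=json.loads(f.attrs["provenance"]))
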