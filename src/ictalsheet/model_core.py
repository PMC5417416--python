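"""Minicolumn model: Wilson-Cowan unit, parameter containers, state classification.

A cortical minicolumn is modelled as a Wilson-Cowan pair (E, I) of fractional
firing activities:

    tau_E dE/dt = -E + Sigm(C_EE*E + C_IE*I + P + A_s*S(t) + lateral E input)
    tau_I dI/dt = -I + Sigm(C_EI*E + C_II*I + Q + lateral I input)

with ``Sigm(x) = 1 / (1 + exp(-a*(x - theta)))``.  ``P`` and ``Q`` are the
baseline drives of the two populations and are the knobs used throughout to
set tissue excitability.  Depending on (P, Q) the deterministic unit (or a
homogeneous sheet of units) is in one of three regimes:

* ``background`` -- a single low-activity equilibrium,
* ``seizure``    -- a single attracting high-activity oscillation,
* ``bistable``   -- background equilibrium and seizure oscillation coexist.

The default parameter set below ("calibrated-v1") was calibrated so that,
at the operating Q, the coupled sheet is bistable for P in (-2.5, -1.1),
monostable background at P = -4 and monostable seizure at P = 1.  Inside
the bistable band the seizure state is spatial: slow re-entrant waves
sustained by the lateral coupling (a homogeneous sheet started in the
quiescent state stays quiescent; an established, spatially disordered
oscillation persists).  Large seizing territories oscillate near 9 Hz
while small strongly driven patches run near 14 Hz, because a small patch
escapes most of the slow lateral drive it would receive inside a large
coherent domain.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy import optimize

__all__ = [
    "ColumnParameters",
    "SheetGeometry",
    "ParameterField",
    "SheetState",
    "StateClass",
    "UnclassifiableError",
    "DEFAULT_PARAMS",
    "DEFAULT_Q",
    "sigmoid",
    "unit_drift",
    "integrate_unit",
    "classify_state",
    "bistable_band",
    "find_fixed_points",
    "background_equilibrium",
    "seizure_cycle_stats",
]

#: Operating baseline drive of the inhibitory population ("calibrated-v1").
DEFAULT_Q: float = -12.4


@dataclass(frozen=True)
class ColumnParameters:
    """Scalar parameters of a single minicolumn (times in ms).

    ``C_IE`` (I to E) and ``C_II`` (I to I) act suppressively and are
    negative; they enter the sigmoid argument directly.  The within-column
    couplings exclude the lateral sheet couplings, which are carried by the
    connectivity matrices; for a homogeneous sheet the effective couplings
    are ``C_EE + w_EE_local + w_EE_remote`` and ``C_EI + w_EI_local``.
    """

    tau_E: float = 10.0
    tau_I: float = 15.0
    C_EE: float = 45.0
    C_IE: float = -60.0
    C_EI: float = 37.0
    C_II: float = -9.0
    a: float = 1.0
    theta: float = 4.0
    A_s: float = 1.0
    name: str = "calibrated-v1"

    def __post_init__(self) -> None:
        if not (self.tau_E > 0 and self.tau_I > 0):
            raise ValueError("time constants must be positive")
        if not self.a > 0:
            raise ValueError("sigmoid steepness a must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ColumnParameters":
        return cls(**d)

    def with_(self, **kw) -> "ColumnParameters":
        return replace(self, **kw)


#: The shipped default parameter set.
DEFAULT_PARAMS = ColumnParameters()


@dataclass(frozen=True)
class SheetGeometry:
    """Lattice dimensions of the simulated cortical sheet.

    A macrocolumn is a ``macro_size x macro_size`` block of minicolumns that
    shares one subcortical noise stream.  ``column_pitch`` is the physical
    minicolumn edge length in micrometres.
    """

    n_rows: int = 150
    n_cols: int = 150
    macro_size: int = 10
    column_pitch: float = 50.0

    def __post_init__(self) -> None:
        if self.n_rows % self.macro_size or self.n_cols % self.macro_size:
            raise ValueError("macro_size must divide both lattice dimensions")

    @property
    def n_columns(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_macro(self) -> int:
        return (self.n_rows // self.macro_size) * (self.n_cols // self.macro_size)

    def macro_index(self) -> np.ndarray:
        """Macrocolumn id of every minicolumn, row-major over the lattice."""
        r = np.arange(self.n_rows) // self.macro_size
        c = np.arange(self.n_cols) // self.macro_size
        n_mc = self.n_cols // self.macro_size
        return (r[:, None] * n_mc + c[None, :]).ravel()

    def rc(self, index: np.ndarray | int):
        """(row, col) of flat row-major column indices."""
        return np.divmod(index, self.n_cols)

    def flat(self, row, col) -> np.ndarray | int:
        return np.asarray(row) * self.n_cols + np.asarray(col)


@dataclass
class ParameterField:
    """One scalar per minicolumn (row-major), instantiating P or Q."""

    values: np.ndarray
    name: str = "P"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.name} field contains non-finite values")

    @classmethod
    def uniform(cls, geometry: SheetGeometry, value: float, name: str = "P"):
        return cls(np.full(geometry.n_columns, float(value)), name=name)


@dataclass
class SheetState:
    """E and I fields of the whole sheet at time t (ms)."""

    E: np.ndarray
    I: np.ndarray
    t: float = 0.0


@dataclass(frozen=True)
class StateClass:
    """Classification of a (P, Q) point: background, bistable or seizure."""

    label: str

    _ORDER = {"background": 0, "bistable": 1, "seizure": 2}

    def __post_init__(self) -> None:
        if self.label not in self._ORDER:
            raise ValueError(f"unknown state label {self.label!r}")

    @property
    def excitability_rank(self) -> int:
        """0 (background) < 1 (bistable) < 2 (seizure)."""
        return self._ORDER[self.label]


class UnclassifiableError(RuntimeError):
    """Raised when the deterministic endpoints cannot be classified."""


def sigmoid(x, a: float = 1.0, theta: float = 4.0):
    """Logistic sigmoid ``1 / (1 + exp(-a*(x - theta)))``, bounded in (0, 1)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("sigmoid input must be finite")
    if a <= 0:
        raise ValueError("sigmoid steepness a must be positive")
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + np.exp(-a * (x - theta)))
    return float(out) if out.ndim == 0 else out


def unit_drift(E, I, P, Q, params: ColumnParameters = DEFAULT_PARAMS,
               s: float = 0.0, lateral_E_input=0.0, lateral_I_input=0.0):
    """Deterministic drift (dE/dt, dI/dt) of one column.

    ``lateral_E_input`` / ``lateral_I_input`` are the connectivity-weighted
    sums of remote excitatory activity supplied by the caller (zero for an
    isolated unit).  ``s`` is the instantaneous noise value.
    """
    p = params
    arg_E = p.C_EE * E + p.C_IE * I + P + p.A_s * s + lateral_E_input
    arg_I = p.C_EI * E + p.C_II * I + Q + lateral_I_input
    dE = (-E + sigmoid(arg_E, p.a, p.theta)) / p.tau_E
    dI = (-I + sigmoid(arg_I, p.a, p.theta)) / p.tau_I
    return dE, dI


def integrate_unit(E0, I0, P, Q, params: ColumnParameters = DEFAULT_PARAMS,
                   duration: float = 4000.0, dt: float = 0.5,
                   lateral_E_gain: float = 0.0, lateral_I_gain: float = 0.0,
                   record: bool = True):
    """Forward-Euler integration of a single deterministic unit.

    ``lateral_E_gain`` / ``lateral_I_gain`` model a homogeneous sheet
    self-consistently: the unit receives ``gain * E`` as lateral input (every
    neighbour carries the same activity as the unit itself).  Returns
    ``(E, I, trace)`` where ``trace`` is the E time series (or None).
    """
    p = params
    n = int(round(duration / dt))
    E, I = float(E0), float(I0)
    trace = np.empty(n) if record else None
    aE = p.a
    for k in range(n):
        arg_E = (p.C_EE + lateral_E_gain) * E + p.C_IE * I + P
        arg_I = (p.C_EI + lateral_I_gain) * E + p.C_II * I + Q
        E += dt * (-E + 1.0 / (1.0 + np.exp(-aE * (arg_E - p.theta)))) / p.tau_E
        I += dt * (-I + 1.0 / (1.0 + np.exp(-aE * (arg_I - p.theta)))) / p.tau_I
        if record:
            trace[k] = E
    return E, I, trace


def _oscillatory(trace: np.ndarray, window: int, amp_threshold: float = 0.1) -> bool:
    """Peak-to-trough range of the final window exceeds the threshold."""
    tail = trace[-window:]
    return float(np.ptp(tail)) > amp_threshold


@functools.lru_cache(maxsize=32)
def _seizure_init_isolated(params: ColumnParameters, Q: float,
                           lateral_E_gain: float, lateral_I_gain: float):
    """Settled state at a deeply seizure-monostable point (P = 1).

    Obtained by integrating from the background state until the oscillation
    is established; reused as the seizure-side initial condition.
    """
    E, I, tr = integrate_unit(0.0, 0.0, 1.0, Q, params,
                              duration=6000.0, dt=0.5,
                              lateral_E_gain=lateral_E_gain,
                              lateral_I_gain=lateral_I_gain)
    if not _oscillatory(tr, window=int(1000 / 0.5)):
        raise UnclassifiableError(
            "no established oscillation at P = 1; parameter set is outside "
            "the calibrated regime")
    return E, I


def classify_state(P: float, Q: float = DEFAULT_Q,
                   params: ColumnParameters = DEFAULT_PARAMS,
                   context: str = "sheet",
                   connectivity=None,
                   duration: float = 8000.0, dt: float = 2.0) -> StateClass:
    """Deterministically classify (P, Q) as background / bistable / seizure.

    Integrates the noise-free system from (i) the background initial
    condition E = I = 0 and (ii) a seizure initial condition sampled from an
    established oscillation at P = 1, and compares endpoint behaviour over
    the final second (oscillatory iff the E peak-to-trough exceeds 0.1; on
    the sheet, iff more than 5% of columns exceed it, since the sustained
    seizure state is spatially asynchronous).

    context
        ``"isolated"``: a single uncoupled unit.
        ``"sheet"`` (default): explicit integration of a coupled sheet --
        the supplied ``connectivity``
        (:class:`~ictalsheet.connectivity.ConnectivityMatrices`) or the
        cached 60x60 reference sheet.  The bistable band is a sheet-level
        statement: inside it the seizure state is sustained by re-entrant
        lateral waves, which an isolated unit cannot express.
    """
    if context not in ("isolated", "sheet"):
        raise ValueError("context must be 'isolated' or 'sheet'")
    if context == "sheet":
        if connectivity is None:
            connectivity = _default_classification_conn()
        return _classify_on_sheet(P, Q, params, connectivity, duration, dt)

    gE = gI = 0.0
    fine_dt = min(dt, 0.5)
    Es, Is = _seizure_init_isolated(params, Q, gE, gI)
    win = int(1000.0 / fine_dt)
    _, _, tr_b = integrate_unit(0.0, 0.0, P, Q, params, duration, fine_dt,
                                lateral_E_gain=gE, lateral_I_gain=gI)
    _, _, tr_s = integrate_unit(Es, Is, P, Q, params, duration, fine_dt,
                                lateral_E_gain=gE, lateral_I_gain=gI)
    return _labels_to_class(_oscillatory(tr_b, win), _oscillatory(tr_s, win),
                            tr_b, tr_s, P, Q)


def _labels_to_class(osc_b, osc_s, tr_b, tr_s, P, Q) -> StateClass:
    if osc_b and not osc_s:
        raise UnclassifiableError(
            f"ambiguous classification at P={P}, Q={Q}: background start "
            "oscillates but seizure start quiesces")
    if osc_b and osc_s:
        return StateClass("seizure")
    if not osc_b and not osc_s:
        # both quiescent: endpoints must agree on the attractor
        if abs(tr_b[-1] - tr_s[-1]) > 0.05:
            raise UnclassifiableError(
                f"two distinct quiescent endpoints at P={P}, Q={Q}; "
                "not classifiable as background/bistable/seizure")
        return StateClass("background")
    return StateClass("bistable")


#: Fixed seed of the (stochastic) seizure-state establishment run; the
#: classification integrations themselves are noise-free, so classify_state
#: is a deterministic function of its inputs.
_ESTABLISHMENT_SEED = 7

_SHEET_SEIZURE_CACHE: dict = {}
_CLASSIFY_CONN_CACHE: dict = {}


def _default_classification_conn(n: int = 60):
    """Reference 60x60 connectivity used by the sheet classification context."""
    if n not in _CLASSIFY_CONN_CACHE:
        from .connectivity import ConnectivityConfig, build_connectivity
        geom = SheetGeometry(n_rows=n, n_cols=n)
        _CLASSIFY_CONN_CACHE[n] = build_connectivity(
            geom, ConnectivityConfig(seed=1))
    return _CLASSIFY_CONN_CACHE[n]


def _sheet_oscillatory(E_frames, fs, amp_threshold=0.1, frac_threshold=0.05):
    """A sheet endpoint is oscillatory when a non-negligible fraction of
    columns shows E swings above the amplitude threshold in the final second.

    In the bistable band the seizure state is spatially asynchronous
    (re-entrant waves), so the per-column swing, not the mean-field swing,
    is the robust criterion.
    """
    win = max(2, int(round(1000.0 * fs / 1000.0)))
    tail = E_frames[-win:]
    col_ptp = np.ptp(tail, axis=0)
    return float((col_ptp > amp_threshold).mean()) > frac_threshold


def _classify_on_sheet(P, Q, params, conn, duration, dt) -> StateClass:
    """Classification by explicit integration of the coupled sheet."""
    from .simulator import NoiseModel, EventSchedule, simulate

    geom = conn.geometry
    n = geom.n_columns
    noise_off = NoiseModel(seed=0, scale=0.0)
    quiet = params.with_(A_s=0.0)

    def run(init, Pval):
        res = simulate(quiet, conn, EventSchedule(), duration, noise_off,
                       dt=dt, geometry=geom,
                       P=ParameterField.uniform(geom, Pval),
                       Q=ParameterField.uniform(geom, Q),
                       init=init)
        return res.E

    zero = SheetState(np.zeros(n), np.zeros(n))
    E_b = run(zero, P)
    est = _sheet_seizure_state(params, conn, Q, dt)
    E_s = run(est, P)
    fs = 1000.0 / dt
    osc_b = _sheet_oscillatory(E_b, fs)
    osc_s = _sheet_oscillatory(E_s, fs)
    return _labels_to_class(osc_b, osc_s, E_b.mean(axis=1), E_s.mean(axis=1),
                            P, Q)


def _sheet_seizure_state(params, conn, Q, dt):
    """Spatially disordered seizure state, established once per sheet at the
    deeply monostable point P = 1 under the stochastic model (fixed seed) and
    reused as the seizure-side initial condition."""
    key = (params, id(conn), Q, dt)
    if key not in _SHEET_SEIZURE_CACHE:
        from .simulator import NoiseModel, EventSchedule, simulate
        geom = conn.geometry
        res = simulate(params, conn, EventSchedule(), 4000.0,
                       NoiseModel(seed=_ESTABLISHMENT_SEED, scale=0.8),
                       dt=dt, geometry=geom,
                       P=ParameterField.uniform(geom, 1.0),
                       Q=ParameterField.uniform(geom, Q),
                       init=SheetState(np.zeros(geom.n_columns),
                                       np.zeros(geom.n_columns)))
        if not _sheet_oscillatory(res.E, 1000.0 / dt):
            raise UnclassifiableError("sheet does not oscillate at P = 1")
        _SHEET_SEIZURE_CACHE[key] = SheetState(res.E[-1].astype(float),
                                               res.I[-1].astype(float))
    return _SHEET_SEIZURE_CACHE[key]


def bistable_band(Q: float = DEFAULT_Q, P_grid=None,
                  params: ColumnParameters = DEFAULT_PARAMS,
                  context: str = "sheet", connectivity=None):
    """Endpoints (P_low, P_high) of the bistable interval on a P grid.

    Returns ``(None, None)`` when no grid point is bistable.  Any
    unclassifiable grid point propagates :class:`UnclassifiableError`.
    """
    if P_grid is None:
        P_grid = np.round(np.arange(-4.0, 0.01, 0.1), 10)
    P_grid = np.asarray(P_grid, dtype=float)
    bis = [float(P) for P in P_grid
           if classify_state(P, Q, params, context, connectivity).label
           == "bistable"]
    if not bis:
        return None, None
    return min(bis), max(bis)


# ---------------------------------------------------------------------------
# fixed-point analysis (used as the independent oracle for classification)

def find_fixed_points(P: float, Q: float,
                      params: ColumnParameters = DEFAULT_PARAMS,
                      lateral_E_gain: float = 0.0, lateral_I_gain: float = 0.0,
                      n_seeds: int = 15, tol: float = 1e-10):
    """All fixed points of the deterministic unit in the unit square.

    Dense multi-start root finding of ``-E + Sigm(...) = 0, -I + Sigm(...) = 0``
    plus Jacobian eigenvalues.  Returns a list of dicts with keys
    ``E, I, eigenvalues, stable``.
    """
    p = params

    def fun(z):
        E, I = z
        arg_E = (p.C_EE + lateral_E_gain) * E + p.C_IE * I + P
        arg_I = (p.C_EI + lateral_I_gain) * E + p.C_II * I + Q
        return [-E + sigmoid(arg_E, p.a, p.theta),
                -I + sigmoid(arg_I, p.a, p.theta)]

    def jac(z):
        E, I = z
        arg_E = (p.C_EE + lateral_E_gain) * E + p.C_IE * I + P
        arg_I = (p.C_EI + lateral_I_gain) * E + p.C_II * I + Q
        sE = sigmoid(arg_E, p.a, p.theta)
        sI = sigmoid(arg_I, p.a, p.theta)
        dE = p.a * sE * (1 - sE)
        dI = p.a * sI * (1 - sI)
        return np.array([
            [(-1 + dE * (p.C_EE + lateral_E_gain)) / p.tau_E,
             dE * p.C_IE / p.tau_E],
            [dI * (p.C_EI + lateral_I_gain) / p.tau_I,
             (-1 + dI * p.C_II) / p.tau_I]])

    grid = np.linspace(0.0, 1.0, n_seeds)
    found = []
    for e0 in grid:
        for i0 in grid:
            sol = optimize.root(fun, [e0, i0], jac=lambda z: jac(z) * np.array(
                [[p.tau_E], [p.tau_I]]), method="hybr", tol=tol)
            if not sol.success:
                continue
            E, I = sol.x
            if not (-0.05 <= E <= 1.05 and -0.05 <= I <= 1.05):
                continue
            if any(abs(E - f["E"]) < 1e-6 and abs(I - f["I"]) < 1e-6
                   for f in found):
                continue
            ev = np.linalg.eigvals(jac((E, I)))
            found.append({"E": float(E), "I": float(I),
                          "eigenvalues": ev,
                          "stable": bool(np.all(ev.real < 0))})
    found.sort(key=lambda f: f["E"])
    return found


def background_equilibrium(P: float, Q: float = DEFAULT_Q,
                           params: ColumnParameters = DEFAULT_PARAMS,
                           lateral_E_gain: float = 0.0,
                           lateral_I_gain: float = 0.0):
    """(E, I) of the low stable equilibrium; integration-refined."""
    E, I, _ = integrate_unit(0.0, 0.0, P, Q, params, duration=6000.0, dt=0.5,
                             lateral_E_gain=lateral_E_gain,
                             lateral_I_gain=lateral_I_gain, record=False)
    return float(E), float(I)


def seizure_cycle_stats(P: float, Q: float = DEFAULT_Q,
                        params: ColumnParameters = DEFAULT_PARAMS,
                        lateral_E_gain: float = 0.0,
                        lateral_I_gain: float = 0.0):
    """Mean / min / max of E over the established seizure cycle at (P, Q).

    Raises :class:`UnclassifiableError` if no oscillation exists there.
    """
    Es, Is = _seizure_init_isolated(params, Q, lateral_E_gain, lateral_I_gain)
    _, _, tr = integrate_unit(Es, Is, P, Q, params, duration=4000.0, dt=0.5,
                              lateral_E_gain=lateral_E_gain,
                              lateral_I_gain=lateral_I_gain)
    tail = tr[-int(1000 / 0.5):]
    if float(np.ptp(tail)) < 0.1:
        raise UnclassifiableError(f"no seizure oscillation at P={P}, Q={Q}")
    return {"mean": float(tail.mean()), "min": float(tail.min()),
            "max": float(tail.max())}
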