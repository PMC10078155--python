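"""Mean-field model of the arcuate KNDy population as the GnRH pulse generator.

The arcuate kisspeptin/neurokinin B/dynorphin (KNDy) network behaves as a
relaxation oscillator: NKB provides fast recurrent excitation of population
firing, while dynorphin accumulates slowly and shuts NKB secretion down,
producing episodic bursts of activity that drive GnRH/LH pulses.  The model
here is a three-variable rate description of that loop,

    dD/dt = ( k_D * H(v; K_vD, n_vD) - D ) / tau_D
    dN/dt = ( (k_N0 + k_N * H(v; K_vN, n_vN)) / (1 + (D/K_DN)**n_DN) - N ) / tau_N
    dv/dt = ( v_max * F(I_net) - v ) / tau_v

with Hill function ``H(x; K, n) = x**n / (K**n + x**n)``, saturating
firing-rate response ``F(I) = H(max(I, 0); K_F, n_F)``, and net input

    I_net = g_Nv * H(N; K_Nv, n_Nv) + I0 + I_exc - I_inh.

NKB secretion has a basal component ``k_N0`` that, like the firing-driven
component, is divisively suppressed by dynorphin; it is what re-ignites the
burst once dynorphin has cleared, and it sets the separation between the
lower (ignition) and upper (depolarisation-silencing) input thresholds.
``I_exc`` and ``I_inh`` are the external excitatory (glutamatergic) and
inhibitory (GABAergic) channels through which afferent circuits such as the
amygdala act on the network.  The model exhibits the characteristic
three-band bifurcation structure in its net input: silent at low drive,
pulsatile in an intermediate band with frequency increasing with excitation,
and a depolarised quiescent-high state above an upper input threshold where
pulsatility terminates.

All times are in minutes; activities are dimensionless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "KndyState",
    "KndyParams",
    "ArcInput",
    "Trajectory",
    "PulseTrain",
    "hill",
    "kndy_derivatives",
    "simulate",
    "pulse_times_from_activity",
    "scan_input",
    "find_fixed_point",
    "RegimeScan",
    "SILENT",
    "PULSATILE",
    "QUIESCENT_HIGH",
]

SILENT = "silent"
PULSATILE = "pulsatile"
QUIESCENT_HIGH = "quiescent_high"

#: Fraction of max(v) used by default for event threshold crossings.
DEFAULT_FRAC_THRESHOLD = 0.5

#: Firing below this fraction of v_max over a whole window is "silent".
SILENT_MAX_FRAC = 0.10


def hill(x: float | np.ndarray, K: float, n: float) -> float | np.ndarray:
    """Hill activation ``x^n / (K^n + x^n)``, defined as 0 for x <= 0."""
    xp = np.maximum(x, 0.0)
    xn = xp**n
    return xn / (K**n + xn)


def _check_finite(obj, names_values) -> None:
    for name, value in names_values:
        if not math.isfinite(value):
            raise ValueError(
                f"{type(obj).__name__}.{name} is not finite: {value!r}"
            )


@dataclass(frozen=True)
class KndyState:
    """Arcuate KNDy population state.

    D: dynorphin activity, N: NKB activity, v: population firing activity.
    All dimensionless and non-negative.
    """

    D: float
    N: float
    v: float

    def __post_init__(self):
        _check_finite(self, [("D", self.D), ("N", self.N), ("v", self.v)])

    def as_array(self) -> np.ndarray:
        return np.array([self.D, self.N, self.v], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "KndyState":
        return cls(D=float(y[0]), N=float(y[1]), v=float(y[2]))


@dataclass(frozen=True)
class ArcInput:
    """External input to KNDy firing: excitatory and inhibitory channels."""

    I_exc: float = 0.0
    I_inh: float = 0.0

    def __post_init__(self):
        _check_finite(self, [("I_exc", self.I_exc), ("I_inh", self.I_inh)])
        if self.I_exc < 0 or self.I_inh < 0:
            raise ValueError(
                f"ArcInput channels must be non-negative, got "
                f"I_exc={self.I_exc}, I_inh={self.I_inh}"
            )


@dataclass(frozen=True)
class KndyParams:
    """Kinetic constants of the KNDy relaxation oscillator.

    Defaults are the committed calibration: at the basal inhibitory tone
    delivered by the amygdala circuit the oscillator pulses every ~25-30 min,
    and at zero external input it still pulses within the ultradian range.
    """

    tau_D: float = 10.0
    tau_N: float = 2.0
    tau_v: float = 1.0
    k_D: float = 1.0
    k_N: float = 1.0
    k_N0: float = 0.125
    v_max: float = 1.0
    K_vD: float = 0.35
    n_vD: float = 4.0
    K_vN: float = 0.12
    n_vN: float = 2.0
    K_DN: float = 0.3
    n_DN: float = 4.0
    K_Nv: float = 0.3
    n_Nv: float = 2.0
    g_Nv: float = 3.0
    K_F: float = 1.0
    n_F: float = 4.0
    I0: float = 0.30

    def __post_init__(self):
        _check_finite(self, [(f.name, getattr(self, f.name)) for f in fields(self)])
        for name in ("tau_D", "tau_N", "tau_v"):
            if getattr(self, name) <= 0:
                raise ValueError(f"KndyParams.{name} must be > 0")
        for name in ("K_vD", "K_vN", "K_DN", "K_Nv", "K_F"):
            if getattr(self, name) <= 0:
                raise ValueError(f"KndyParams.{name} must be > 0")
        for name in ("n_vD", "n_vN", "n_DN", "n_Nv", "n_F"):
            if getattr(self, name) < 1:
                raise ValueError(f"KndyParams.{name} must be >= 1")
        for name in ("k_D", "k_N", "v_max", "g_Nv", "I0"):
            if getattr(self, name) < 0:
                raise ValueError(f"KndyParams.{name} must be >= 0")

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "KndyParams":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class Trajectory:
    """Simulated trajectory on a uniform output grid (times in minutes)."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), ndim); columns 0..2 are D, N, v
    columns: tuple[str, ...] = ("D", "N", "v")

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        states = np.atleast_2d(np.asarray(self.states, dtype=float))
        if times.ndim != 1 or len(times) != states.shape[0]:
            raise ValueError("times and states must have matching lengths")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(states))):
            raise ValueError("trajectory contains non-finite values")
        if states.shape[1] != len(self.columns):
            raise ValueError("state dimension does not match column labels")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "states", states)

    @property
    def v(self) -> np.ndarray:
        return self.states[:, self.columns.index("v")]

    def column(self, name: str) -> np.ndarray:
        return self.states[:, self.columns.index(name)]


@dataclass(frozen=True)
class PulseTrain:
    """Strictly increasing event (pulse) times in minutes."""

    times: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1:
            raise ValueError("PulseTrain.times must be one-dimensional")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("PulseTrain.times must be strictly increasing")
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return int(self.times.size)

    def intervals(self) -> np.ndarray:
        return np.diff(self.times)


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the failure time."""

    def __init__(self, message: str, t_fail: float):
        super().__init__(message)
        self.t_fail = t_fail


def net_input(state: KndyState | Sequence[float], params: KndyParams,
              inp: ArcInput) -> float:
    """Net drive onto the firing variable (recurrent NKB + external)."""
    N = state.N if isinstance(state, KndyState) else float(state[1])
    rec = params.g_Nv * hill(N, params.K_Nv, params.n_Nv)
    return float(rec + params.I0 + inp.I_exc - inp.I_inh)


def _rhs(y: np.ndarray, p: KndyParams, I_exc: float, I_inh: float) -> np.ndarray:
    D, N, v = y
    dD = (p.k_D * hill(v, p.K_vD, p.n_vD) - D) / p.tau_D
    dN = ((p.k_N0 + p.k_N * hill(v, p.K_vN, p.n_vN))
          / (1.0 + (max(D, 0.0) / p.K_DN) ** p.n_DN) - N) / p.tau_N
    I_net = p.g_Nv * hill(N, p.K_Nv, p.n_Nv) + p.I0 + I_exc - I_inh
    dv = (p.v_max * hill(I_net, p.K_F, p.n_F) - v) / p.tau_v
    return np.array([dD, dN, dv])


def kndy_derivatives(state: KndyState, params: KndyParams,
                     inp: ArcInput | None = None) -> KndyState:
    """Time derivative of the KNDy state.

    Monotone by construction: increasing ``I_exc`` never decreases dv/dt
    and increasing ``I_inh`` never increases it, at fixed state.
    """
    if inp is None:
        inp = ArcInput()
    d = _rhs(state.as_array(), params, inp.I_exc, inp.I_inh)
    return KndyState.from_array(d)


def simulate(
    params: KndyParams,
    input_fn: Callable[[float], ArcInput] | ArcInput | None = None,
    t_span: tuple[float, float] = (0.0, 300.0),
    dt_out: float = 0.1,
    tol: float = 1e-6,
    y0: KndyState | None = None,
    segment_bounds: Sequence[float] = (),
) -> Trajectory:
    """Integrate the KNDy ODEs and resample onto a uniform grid.

    Parameters
    ----------
    input_fn
        Either a constant :class:`ArcInput`, ``None`` (zero input), or a
        callable ``t -> ArcInput``.  If the input is discontinuous, pass the
        switch times in ``segment_bounds`` so the solver restarts there.
    tol
        Relative tolerance of the adaptive Runge-Kutta integrator; the
        absolute tolerance is ``tol * 1e-2``.
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not t1 > t0:
        raise ValueError(f"t_span must be ordered, got {t_span}")
    if dt_out <= 0:
        raise ValueError("dt_out must be > 0")
    if y0 is None:
        y0 = KndyState(D=0.0, N=0.0, v=0.0)

    if input_fn is None:
        input_fn = ArcInput()
    if isinstance(input_fn, ArcInput):
        const = input_fn
        input_fn = lambda t: const  # noqa: E731

    n_out = int(round((t1 - t0) / dt_out))
    times = t0 + dt_out * np.arange(n_out + 1)
    times[-1] = min(times[-1], t1)

    bounds = sorted({t0, t1, *[float(b) for b in segment_bounds if t0 < b < t1]})
    out = np.empty((len(times), 3))
    y = y0.as_array()
    for a, b in zip(bounds[:-1], bounds[1:]):
        # input is held piecewise-smooth inside each segment; evaluate just
        # after the left edge so step changes take effect at their onset
        def rhs(t, yy):
            inp = input_fn(t)
            return _rhs(yy, params, inp.I_exc, inp.I_inh)

        mask = (times >= a - 1e-12) & (times <= b + 1e-12)
        sol = solve_ivp(
            rhs, (a, b), y, method="RK45", dense_output=True,
            rtol=tol, atol=tol * 1e-2, max_step=5.0,
        )
        if not sol.success:
            raise IntegrationError(
                f"ODE integration failed at t={sol.t[-1]:.3f} min: {sol.message}",
                t_fail=float(sol.t[-1]),
            )
        out[mask] = sol.sol(np.clip(times[mask], a, b)).T
        y = sol.y[:, -1]

    out = np.maximum(out, 0.0)  # clip solver noise below zero
    return Trajectory(times=times, states=out)


def pulse_times_from_activity(
    traj: Trajectory, frac_threshold: float = DEFAULT_FRAC_THRESHOLD
) -> PulseTrain:
    """Event times of pulse-generator activity bursts.

    An event is an upward crossing of ``frac_threshold * max(v)`` that is
    later followed by a downward crossing (i.e. a completed burst); a
    terminal rise into a sustained high plateau is not an event.  Returns an
    empty train when v never crosses the threshold.
    """
    if not 0.0 < frac_threshold < 1.0:
        raise ValueError("frac_threshold must be in (0, 1)")
    v = traj.v
    if v.size < 2:
        raise ValueError("trajectory must contain at least 2 samples")
    vmax = float(v.max())
    if vmax <= 0:
        return PulseTrain(times=np.empty(0))
    thr = frac_threshold * vmax
    above = v >= thr
    up = np.flatnonzero(~above[:-1] & above[1:]) + 1
    down = np.flatnonzero(above[:-1] & ~above[1:]) + 1
    # keep only upward crossings followed by a return below threshold
    events = [traj.times[i] for i in up if down.size and down[down > i].size]
    return PulseTrain(times=np.asarray(events))


def find_fixed_point(
    params: KndyParams,
    inp: ArcInput,
    guess: KndyState | None = None,
    tol: float = 1e-12,
) -> KndyState | None:
    """Locate a fixed point of the KNDy vector field by root finding.

    Returns ``None`` if the search does not converge to a non-negative root.
    Serves as the steady-state oracle for regime classification tests.
    """
    from scipy.optimize import root

    if guess is None:
        guess = KndyState(D=0.0, N=0.0, v=0.0)
    sol = root(lambda y: _rhs(y, params, inp.I_exc, inp.I_inh),
               guess.as_array(), tol=tol)
    if not sol.success or np.any(sol.x < -1e-9):
        return None
    return KndyState.from_array(np.maximum(sol.x, 0.0))


#: Minimum peak-to-trough excursion (fraction of v_max) that counts as a
#: burst cycle even when fewer than two events complete in the window.
PULSATILE_EXCURSION_FRAC = 0.25


def classify_activity(window: Trajectory, v_max: float,
                      frac_threshold: float = DEFAULT_FRAC_THRESHOLD) -> str:
    """Regime of the firing activity within an already-extracted window.

    ``silent``: v stays below 10% of v_max.  ``pulsatile``: at least two
    completed burst events, or a single large excursion (slow bursting
    that does not complete twice in the window).  ``quiescent_high``:
    sustained activity without bursting - the depolarisation-silenced
    state above the upper input threshold, including the low-amplitude
    oscillatory shoulder adjacent to it.
    """
    v = window.v
    peak, trough = float(v.max()), float(v.min())
    if peak < SILENT_MAX_FRAC * v_max:
        return SILENT
    events = pulse_times_from_activity(window, frac_threshold)
    if len(events) >= 2 or peak - trough >= PULSATILE_EXCURSION_FRAC * v_max:
        return PULSATILE
    return QUIESCENT_HIGH


@dataclass(frozen=True)
class RegimeScan:
    """Result of an input scan: per-grid-point oscillation frequency and regime."""

    I_exc: np.ndarray
    frequency: np.ndarray  # events per minute over the analysis window
    regime: tuple[str, ...]

    def band(self, label: str) -> np.ndarray:
        return self.I_exc[np.array([r == label for r in self.regime])]


def scan_input(
    params: KndyParams,
    I_exc_grid: Sequence[float],
    I_inh: float = 0.0,
    t_settle: float = 120.0,
    t_window: float = 120.0,
    dt_out: float = 0.1,
    tol: float = 1e-6,
) -> RegimeScan:
    """Scan the excitatory input channel and classify the dynamical regime.

    For each grid point the model is run from a cold start, the first
    ``t_settle`` minutes are discarded, and the remaining window is
    classified as silent, pulsatile or quiescent-high; frequency is the
    completed-event rate in the window.
    """
    grid = np.asarray(list(I_exc_grid), dtype=float)
    if grid.size < 2:
        raise ValueError("I_exc_grid must contain at least 2 points")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("I_exc_grid must be sorted ascending")

    freqs = np.zeros(grid.size)
    regimes: list[str] = []
    for i, ie in enumerate(grid):
        inp = ArcInput(I_exc=float(ie), I_inh=float(I_inh))
        traj = simulate(params, inp, (0.0, t_settle + t_window),
                        dt_out=dt_out, tol=tol)
        mask = traj.times >= t_settle
        window = Trajectory(times=traj.times[mask], states=traj.states[mask])
        label = classify_activity(window, params.v_max)
        regimes.append(label)
        if label == PULSATILE:
            events = pulse_times_from_activity(window)
            freqs[i] = len(events) / t_window
    return RegimeScan(I_exc=grid, frequency=freqs, regime=tuple(regimes))
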