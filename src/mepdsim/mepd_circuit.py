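"""Firing-rate model of the posterodorsal medial amygdala (MePD) circuit.

The circuit couples a kisspeptin (Kiss1) population to the arcuate KNDy
pulse generator through three pathways:

  (i)  a GABA-GABA disinhibitory chain: Kiss1 drives local GABA
       interneurons (G1) that inhibit the GABAergic efferent projection
       population (G2), so Kiss1 activation *reduces* inhibitory tone onto
       the pulse generator;
  (ii) glutamatergic interneurons (E) that excite the GABAergic efferents,
       counteracting the disinhibition; and
  (iii) direct glutamatergic projections (E) onto the arcuate network.

The G1 -> G2 inhibitory weight is split into a GABA_A-like (fast,
bicuculline-sensitive) and a GABA_B-like (slow, CGP-35348-sensitive)
component; receptor antagonists are modelled as fractional blockades of
the corresponding synaptic weights, stepped on at the bolus time and held
for the rest of the session.  Intra-MePD glutamate blockade (AP5+CNQX)
removes the E -> G2 synapse but not the E -> arcuate projection, because
infused antagonists act only on receptors inside the MePD.

All populations relax with a common time constant toward rectified
logistic functions of their summed input; activities are dimensionless in
[0, 1] and time is in minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np

from .kndy_model import (
    ArcInput,
    IntegrationError,
    KndyParams,
    Trajectory,
    _rhs as _kndy_rhs,
    classify_activity,
)

__all__ = [
    "MepdState",
    "MepdParams",
    "DrugCondition",
    "StimProtocol",
    "mepd_derivatives",
    "mepd_output",
    "mepd_steady_state",
    "simulate_coupled",
    "classify_regime",
    "coupled_trajectory_columns",
    "PRESETS",
    "preset_protocol",
]

COUPLED_COLUMNS = ("D", "N", "v", "K", "G1", "E", "G2")


def _logistic(x: float | np.ndarray) -> float | np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class MepdState:
    """MePD population activities: Kiss1 (K), GABA interneurons (G1),
    glutamatergic population (E), GABAergic efferents (G2)."""

    K: float
    G1: float
    E: float
    G2: float

    def __post_init__(self):
        for name in ("K", "G1", "E", "G2"):
            val = getattr(self, name)
            if not math.isfinite(val):
                raise ValueError(f"MepdState.{name} is not finite: {val!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.K, self.G1, self.E, self.G2], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "MepdState":
        return cls(K=float(y[0]), G1=float(y[1]), E=float(y[2]), G2=float(y[3]))


@dataclass(frozen=True)
class MepdParams:
    """MePD circuit weights, gains and sigmoid parameters.

    The defaults are the committed calibration obtained jointly with the
    KNDy defaults: the unstimulated circuit delivers a basal GABAergic tone
    that puts the pulse generator at a ~27-min interpulse interval, optical
    Kiss1 drive shortens it to ~20 min, GABA_A blockade during drive
    reverses the net output to inhibitory, GABA_B blockade during drive
    approximately cancels it, and glutamate blockade during drive pushes
    the pulse generator over its upper (depolarisation-silencing) input
    threshold.
    """

    tau_m: float = 2.0
    kappa0: float = 0.0
    kappa_opt: float = 1.0
    w_KG1: float = 6.0
    w_A: float = 0.5925
    w_B: float = 0.3491
    w_KE: float = 6.0
    e0: float = 0.0
    w_EG2: float = 0.9220
    g0: float = 1.0
    w_G2out: float = 0.8
    w_Eout: float = 0.25
    slope_G1: float = 8.0
    theta_G1: float = 3.0
    slope_E: float = 8.0
    theta_E: float = 3.0
    slope_G2: float = 4.0
    theta_G2: float = 1.0949

    def __post_init__(self):
        if self.tau_m <= 0:
            raise ValueError("MepdParams.tau_m must be > 0")
        if self.w_A + self.w_B <= 0:
            raise ValueError("MepdParams requires w_A + w_B > 0")
        for name in ("kappa0", "kappa_opt", "w_KG1", "w_A", "w_B", "w_KE",
                     "w_EG2", "w_G2out", "w_Eout", "slope_G1", "slope_E",
                     "slope_G2"):
            val = getattr(self, name)
            if not math.isfinite(val) or val < 0:
                raise ValueError(f"MepdParams.{name} must be finite and >= 0")

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "MepdParams":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class DrugCondition:
    """Receptor-antagonist blockade fractions.

    beta_A: GABA_A-mediated G1->G2 inhibition blocked (bicuculline);
    beta_B: GABA_B-mediated inhibition blocked (CGP-35348);
    beta_glu: intra-MePD glutamatergic E->G2 transmission blocked
    (AP5+CNQX cocktail); onset_min: bolus onset time.
    """

    beta_A: float = 0.0
    beta_B: float = 0.0
    beta_glu: float = 0.0
    onset_min: float = 50.0

    def __post_init__(self):
        for name in ("beta_A", "beta_B", "beta_glu"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"DrugCondition.{name} must be in [0, 1], "
                                 f"got {val}")

    @property
    def is_null(self) -> bool:
        return self.beta_A == self.beta_B == self.beta_glu == 0.0


NO_DRUG = DrugCondition()


@dataclass(frozen=True)
class StimProtocol:
    """Timed optogenetic and infusion events of one 150-min session:
    a 60-min control window, drug bolus 10 min before light onset, then
    90 min of (optional) sustained optical stimulation with continuous
    drug infusion."""

    drug: DrugCondition = NO_DRUG
    light: bool = False
    t_total: float = 150.0
    control_end: float = 60.0
    light_on: float = 60.0
    light_off: float = 150.0
    drug_onset: float = 50.0

    def __post_init__(self):
        if not (0.0 <= self.drug_onset <= self.light_on
                <= self.light_off <= self.t_total):
            raise ValueError(
                "protocol must satisfy 0 <= drug_onset <= light_on "
                f"<= light_off <= t_total, got {self}")

    def light_at(self, t: float) -> bool:
        return self.light and self.light_on <= t < self.light_off

    def drug_at(self, t: float) -> DrugCondition:
        return self.drug if t >= self.drug_onset else NO_DRUG

    @property
    def switch_times(self) -> tuple[float, ...]:
        return tuple(sorted({self.drug_onset, self.light_on, self.light_off}))


def _g2_drive(K: float, G1: float, E: float, p: MepdParams,
              drug: DrugCondition) -> float:
    w_inh = (1.0 - drug.beta_A) * p.w_A + (1.0 - drug.beta_B) * p.w_B
    return p.g0 + (1.0 - drug.beta_glu) * p.w_EG2 * E - w_inh * G1


def _mepd_targets(y: np.ndarray, p: MepdParams, drug: DrugCondition,
                  light_on: bool) -> np.ndarray:
    K, G1, E, G2 = y
    k_target = p.kappa0 + (p.kappa_opt if light_on else 0.0)
    g1_target = _logistic(p.slope_G1 * (p.w_KG1 * K - p.theta_G1))
    e_target = _logistic(p.slope_E * (p.w_KE * K + p.e0 - p.theta_E))
    g2_target = _logistic(p.slope_G2 * (_g2_drive(K, G1, E, p, drug)
                                        - p.theta_G2))
    return np.array([k_target, g1_target, e_target, g2_target])


def mepd_derivatives(state: MepdState, params: MepdParams,
                     drug: DrugCondition = NO_DRUG,
                     light_on: bool = False) -> MepdState:
    """Time derivative of the MePD state (relaxation to sigmoid targets)."""
    y = state.as_array()
    d = (_mepd_targets(y, params, drug, light_on) - y) / params.tau_m
    return MepdState.from_array(d)


def mepd_output(state: MepdState, params: MepdParams) -> ArcInput:
    """Input delivered to the arcuate network: glutamatergic excitation
    from E and GABAergic inhibition from the efferent population G2."""
    return ArcInput(I_exc=params.w_Eout * max(state.E, 0.0),
                    I_inh=params.w_G2out * max(state.G2, 0.0))


def mepd_steady_state(params: MepdParams, drug: DrugCondition = NO_DRUG,
                      light_on: bool = False) -> MepdState:
    """Closed-form steady state of the (feed-forward) MePD circuit."""
    K = params.kappa0 + (params.kappa_opt if light_on else 0.0)
    G1 = float(_logistic(params.slope_G1 * (params.w_KG1 * K - params.theta_G1)))
    E = float(_logistic(params.slope_E * (params.w_KE * K + params.e0
                                          - params.theta_E)))
    G2 = float(_logistic(params.slope_G2 * (_g2_drive(K, G1, E, params, drug)
                                            - params.theta_G2)))
    return MepdState(K=K, G1=G1, E=E, G2=G2)


def _coupled_rhs(y: np.ndarray, kndy: KndyParams, mepd: MepdParams,
                 drug: DrugCondition, light_on: bool) -> np.ndarray:
    arc = y[:3]
    pop = y[3:]
    E, G2 = pop[2], pop[3]
    I_exc = mepd.w_Eout * max(E, 0.0)
    I_inh = mepd.w_G2out * max(G2, 0.0)
    d_arc = _kndy_rhs(arc, kndy, I_exc, I_inh)
    d_pop = (_mepd_targets(pop, mepd, drug, light_on) - pop) / mepd.tau_m
    return np.concatenate([d_arc, d_pop])


def control_initial_state(kndy: KndyParams, mepd: MepdParams,
                          burn_in: float = 240.0,
                          tol: float = 1e-6) -> np.ndarray:
    """State on the control (light off, no drug) attractor, obtained by
    integrating the coupled system from rest for ``burn_in`` minutes."""
    from scipy.integrate import solve_ivp

    m0 = mepd_steady_state(mepd, NO_DRUG, light_on=False)
    y0 = np.concatenate([np.zeros(3), m0.as_array()])
    sol = solve_ivp(
        lambda t, y: _coupled_rhs(y, kndy, mepd, NO_DRUG, False),
        (0.0, burn_in), y0, method="RK45", rtol=tol, atol=tol * 1e-2,
        max_step=5.0)
    if not sol.success:
        raise IntegrationError("burn-in integration failed", float(sol.t[-1]))
    return sol.y[:, -1]


def simulate_coupled(
    kndy: KndyParams,
    mepd: MepdParams,
    protocol: StimProtocol,
    t_span: tuple[float, float] | None = None,
    dt_out: float = 0.1,
    tol: float = 1e-6,
    y0: np.ndarray | None = None,
    burn_in: float = 240.0,
) -> Trajectory:
    """Integrate the 7-dimensional coupled MePD-KNDy system.

    Drug and light are switched at the protocol times (the solver restarts
    at each switch).  Unless ``y0`` is given, the run starts on the control
    attractor reached after ``burn_in`` minutes without stimulation, so the
    control window shows steady pulsing from t = 0.  Deterministic for
    fixed arguments.
    """
    from scipy.integrate import solve_ivp

    if t_span is None:
        t_span = (0.0, protocol.t_total)
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not t1 > t0:
        raise ValueError(f"t_span must be ordered, got {t_span}")
    if dt_out <= 0:
        raise ValueError("dt_out must be > 0")
    if y0 is None:
        y0 = control_initial_state(kndy, mepd, burn_in=burn_in, tol=tol)

    n_out = int(round((t1 - t0) / dt_out))
    times = t0 + dt_out * np.arange(n_out + 1)
    bounds = sorted({t0, t1, *[s for s in protocol.switch_times if t0 < s < t1]})
    out = np.empty((len(times), 7))
    y = np.asarray(y0, dtype=float)
    for a, b in zip(bounds[:-1], bounds[1:]):
        mid = 0.5 * (a + b)
        drug = protocol.drug_at(mid)
        light_on = protocol.light_at(mid)
        sol = solve_ivp(
            lambda t, yy: _coupled_rhs(yy, kndy, mepd, drug, light_on),
            (a, b), y, method="RK45", dense_output=True,
            rtol=tol, atol=tol * 1e-2, max_step=5.0)
        if not sol.success:
            raise IntegrationError(
                f"coupled integration failed at t={sol.t[-1]:.3f} min: "
                f"{sol.message}", t_fail=float(sol.t[-1]))
        mask = (times >= a - 1e-12) & (times <= b + 1e-12)
        out[mask] = sol.sol(np.clip(times[mask], a, b)).T
        y = sol.y[:, -1]

    out = np.maximum(out, 0.0)
    return Trajectory(times=times, states=out, columns=COUPLED_COLUMNS)


def classify_regime(
    traj: Trajectory,
    window: tuple[float, float],
    v_max: float = 1.0,
    frac_threshold: float = 0.5,
) -> str:
    """Classify pulse-generator dynamics within a window.

    ``silent``: firing stays below 10% of v_max.  ``pulsatile``: completed
    burst events, or a large peak-to-trough excursion (a slow burst cycle
    that does not complete twice within the window).  ``quiescent_high``:
    elevated activity without bursting - the depolarisation-silenced state
    above the upper input threshold, including the low-amplitude
    oscillatory shoulder next to it.
    """
    w0, w1 = float(window[0]), float(window[1])
    if w1 - w0 < 30.0:
        raise ValueError("classification window must span at least 30 min")
    mask = (traj.times >= w0) & (traj.times <= w1)
    if not mask.any() or traj.times[0] > w0 or traj.times[-1] < w1:
        raise ValueError("window must lie inside the trajectory")
    sub = Trajectory(times=traj.times[mask], states=traj.states[mask],
                     columns=traj.columns)
    return classify_activity(sub, v_max, frac_threshold)


# --- Experimental-arm presets -------------------------------------------

def _load_condition(text: str) -> tuple[bool, DrugCondition]:
    import yaml

    cfg = yaml.safe_load(text)
    light = bool(cfg.pop("light"))
    return light, DrugCondition(**{k: float(v) for k, v in cfg.items()})


def load_preset_file(path) -> tuple[bool, DrugCondition]:
    """Read an arm condition (light flag + blockade fractions) from YAML."""
    from pathlib import Path

    return _load_condition(Path(path).read_text())


def _builtin_presets() -> dict[str, tuple[bool, DrugCondition]]:
    from importlib import resources

    presets = {}
    root = resources.files(__package__) / "presets"
    for entry in sorted(root.iterdir(), key=lambda e: e.name):
        if entry.name.endswith(".yaml"):
            presets[entry.name[:-5]] = _load_condition(entry.read_text())
    return presets


#: The eight experimental arms: sustained 5-Hz optical stimulation of MePD
#: Kiss1 neurons with/without vehicle (aCSF) or receptor antagonists, and
#: each antagonist alone.  Loaded from the packaged condition files.
PRESETS: dict[str, tuple[bool, DrugCondition]] = _builtin_presets()


def preset_protocol(name: str) -> StimProtocol:
    """The standard 150-min session protocol for a named experimental arm."""
    try:
        light, drug = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown arm {name!r}; available presets: "
            f"{', '.join(sorted(PRESETS))}") from None
    return StimProtocol(drug=drug, light=light)
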