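"""Biophysics of the CA1 PV-interneuron model.

Single compartment with four currents:

    C_M dV/dt = I_app - I_leak - I_Kv3 - I_Kv1 - I_Na      (densities)

    I_leak = g_L (V - E_L)
    I_Kv3  = g_Kv3 n^2 (V - E_K)        fast delayed rectifier
    I_Kv1  = g_Kv1 p q (V - E_K)        slowly inactivating K current
    I_Na   = g_Na m^3 h (V - E_Na)      transient sodium

Each gate relaxes toward its voltage-dependent steady state,
dx/dt = (x_inf(V) - x) / tau_x(V).  The Kv1 inactivation gate q is the
slow variable of the system: its time constant k*(V+105) reaches
hundreds of milliseconds at depolarized potentials, which is what makes
persistent interruption of firing and elliptical bursting possible.

Functions here accept scalars or numpy arrays for V.  The compiled
integration kernel in :mod:`pvin.integrate` inlines the same formulas;
a regression test asserts the two agree to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import PVINParameters

__all__ = [
    "ModelState", "CurrentBreakdown", "GATES",
    "gate_steady_state", "gate_time_constant", "currents", "rhs",
    "temperature_scale", "steady_gates", "equilibrium_q_of_V",
]

GATES = ("m", "h", "n", "p", "q")
STATE_VARS = ("V", "m", "h", "n", "p", "q")


@dataclass
class ModelState:
    """Dynamical state (V in mV, gates dimensionless in [0, 1])."""

    V: float
    m: float
    h: float
    n: float
    p: float
    q: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite model state: {arr}")
        if not (-150.0 <= self.V <= 80.0):
            raise ValueError(f"V = {self.V} mV outside plausible range")
        gates = arr[1:]
        if np.any(gates < 0) or np.any(gates > 1):
            raise ValueError(f"gate outside [0, 1]: {gates}")

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.m, self.h, self.n, self.p, self.q])

    @classmethod
    def from_array(cls, arr) -> "ModelState":
        return cls(*(float(x) for x in arr))


@dataclass
class CurrentBreakdown:
    """Whole-cell currents in pA (density x area)."""

    I_leak: float
    I_Kv3: float
    I_Kv1: float
    I_Na: float
    I_app: float

    @property
    def total_ionic(self) -> float:
        return self.I_leak + self.I_Kv3 + self.I_Kv1 + self.I_Na


# ----------------------------------------------------------------------
# Gating functions
# ----------------------------------------------------------------------

def gate_steady_state(gate_id: str, V, params: PVINParameters | None = None):
    """Steady-state activation/inactivation x_inf(V) for a gate."""
    p = params or PVINParameters()
    if gate_id == "m":
        return 1.0 / (1.0 + np.exp(-(V - p.V_h) / 11.5))
    if gate_id == "h":
        return 1.0 / (1.0 + np.exp((V + 58.3) / 6.7))
    if gate_id == "n":
        return 1.0 / (1.0 + np.exp(-(V + 12.4) / 6.8))
    if gate_id == "p":
        return (1.0 + np.exp(-(V + 41.4) / 26.6)) ** -4
    if gate_id == "q":
        return 1.0 / (1.0 + np.exp((V + 78.5) / 6.0))
    raise ValueError(f"unknown gate {gate_id!r}; expected one of {GATES}")


def gate_time_constant(gate_id: str, V, params: PVINParameters | None = None):
    """Voltage-dependent time constant tau_x(V) in ms (Q10-scaled)."""
    p = params or PVINParameters()
    s = p.tau_scale
    if gate_id == "m":
        return s * p.tau_m * np.ones_like(np.asarray(V, dtype=float))
    if gate_id == "h":
        return s * (p.tau_h_floor + p.tau_h_amp
                    / (1.0 + np.exp((V + 60.0) / 12.0)))
    if gate_id == "n":
        return s * (
            (0.087 + 11.4 / (1.0 + np.exp((V + 14.6) / 8.6)))
            * (0.087 + 11.4 / (1.0 + np.exp(-(V - 1.3) / 18.7)))
        )
    if gate_id == "p":
        return s * p.tau_p * np.ones_like(np.asarray(V, dtype=float))
    if gate_id == "q":
        if p.tau_q_mode == "constant":
            raw = p.tau_q_const * np.ones_like(np.asarray(V, dtype=float))
        else:
            raw = p.k * (np.asarray(V, dtype=float) + 105.0)
        return s * np.maximum(raw, p.tau_q_floor)
    raise ValueError(f"unknown gate {gate_id!r}; expected one of {GATES}")


def steady_gates(V, params: PVINParameters | None = None) -> dict:
    return {g: gate_steady_state(g, V, params) for g in GATES}


# ----------------------------------------------------------------------
# Currents and the vector field
# ----------------------------------------------------------------------

def _ionic_densities(V, m, h, n, p_gate, q, p: PVINParameters):
    """Ionic current densities in µA/cm^2."""
    I_leak = p.g_L * (V - p.E_L)
    I_Kv3 = p.g_Kv3 * n ** 2 * (V - p.E_K)
    I_Kv1 = p.g_Kv1 * p_gate * q * (V - p.E_K)
    I_Na = p.g_Na * m ** 3 * h * (V - p.E_Na)
    return I_leak, I_Kv3, I_Kv1, I_Na


def currents(state: ModelState, I_app_pA: float,
             params: PVINParameters | None = None) -> CurrentBreakdown:
    """Whole-cell current breakdown (pA) at a given state."""
    p = params or PVINParameters()
    dens = _ionic_densities(state.V, state.m, state.h, state.n,
                            state.p, state.q, p)
    to_pA = p.area * 1e6  # µA/cm^2 -> pA
    return CurrentBreakdown(
        I_leak=dens[0] * to_pA, I_Kv3=dens[1] * to_pA,
        I_Kv1=dens[2] * to_pA, I_Na=dens[3] * to_pA, I_app=I_app_pA,
    )


def rhs(state, I_app_pA: float, params: PVINParameters | None = None,
        frozen_q: float | None = None, instant_m: bool = False) -> np.ndarray:
    """Time derivative of the state vector [V, m, h, n, p, q].

    ``frozen_q`` fixes the slow Kv1 inactivation gate at a constant
    value (dq/dt = 0): this is the fast subsystem used throughout the
    fast/slow bifurcation analysis.  ``instant_m`` slaves the Na
    activation gate to m_inf(V), removing the 1 µs stiffness.
    """
    p = params or PVINParameters()
    if isinstance(state, ModelState):
        arr = state.as_array()
    else:
        arr = np.asarray(state, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite state passed to rhs: {arr}")
    V, m, h, n, pg, q = arr
    if frozen_q is not None:
        q = frozen_q
    if instant_m:
        m = gate_steady_state("m", V, p)

    dens = _ionic_densities(V, m, h, n, pg, q, p)
    I_app_den = I_app_pA * p.pA_to_uA_per_cm2
    dV = (I_app_den - sum(dens)) / p.C_M

    d = np.empty(6)
    d[0] = dV
    for i, g in enumerate(GATES, start=1):
        x = (m, h, n, pg, q)[i - 1]
        d[i] = (gate_steady_state(g, V, p) - x) / gate_time_constant(g, V, p)
    if instant_m:
        d[1] = 0.0
    if frozen_q is not None:
        d[5] = 0.0
    return d


def temperature_scale(params: PVINParameters, T: float) -> PVINParameters:
    """Parameter set rerun at temperature T (°C).

    Every gating time constant is divided by Q10^((T - T_base)/10);
    conductances, reversals and steady-state curves are unchanged.
    """
    return params.replace(temperature=T)


# ----------------------------------------------------------------------
# Equilibrium structure of the fast subsystem
# ----------------------------------------------------------------------

def equilibrium_q_of_V(V, I_app_pA: float,
                       params: PVINParameters | None = None):
    """Closed-form q on the frozen-q equilibrium branch, as a graph over V.

    At an equilibrium of the fast subsystem every fast gate sits on its
    steady-state curve and the current balance holds.  Because I_Kv1 is
    linear in q, the balance can be solved for q explicitly:

        q = (I_app - I_leak - I_Kv3 - I_Na) / (g_Kv1 p_inf(V) (V - E_K))

    This parametrisation traces the entire equilibrium branch, including
    folds, and serves as an independent oracle for the predictor-
    corrector continuation.
    """
    p = params or PVINParameters()
    m = gate_steady_state("m", V, p)
    h = gate_steady_state("h", V, p)
    n = gate_steady_state("n", V, p)
    pg = gate_steady_state("p", V, p)
    I_leak, I_Kv3, _, I_Na = _ionic_densities(V, m, h, n, pg, 0.0, p)
    I_app_den = I_app_pA * p.pA_to_uA_per_cm2
    denom = p.g_Kv1 * pg * (V - p.E_K)
    return (I_app_den - I_leak - I_Kv3 - I_Na) / denom
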