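"""Fixed-step time integration of the PV-IN models.

Deterministic runs use classic RK4; stochastic runs use forward Euler
with one independent Gaussian current sample per step, so that a
(protocol, dt, seed) triple is bit-reproducible.  A Rush-Larsen
exponential-Euler mode integrates the gates unconditionally stably and
is used when the 1 µs Na-activation gate is integrated explicitly
instead of being slaved to m_inf(V).

The inner loop is compiled with numba; the formulas mirror
:mod:`pvin.model_core` and a regression test holds the two to machine
precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import model_core
from .params import PVINParameters
from .stimulus import StimulusProtocol

__all__ = ["SimulationResult", "integrate", "detect_spikes", "fi_curve",
           "resting_state"]

# indices into the flat parameter vector (see params.PARAM_LAYOUT)
_iCM, _iAREA, _iGL, _iGKV3, _iGKV1, _iGNA = 0, 1, 2, 3, 4, 5
_iEL, _iEK, _iENA, _iVH, _iK = 6, 7, 8, 9, 10
_iTAUM, _iTAUP, _iTAUQF, _iTSC, _iTQMODE, _iTQC = 11, 12, 13, 14, 15, 16
_iTHF, _iTHA = 17, 18

RK4, EULER, EXP_EULER = 0, 1, 2
_METHODS = {"rk4": RK4, "euler": EULER, "exp_euler": EXP_EULER}


@njit(cache=True)
def _gates_inf_tau(P, V):
    minf = 1.0 / (1.0 + np.exp(-(V - P[_iVH]) / 11.5))
    hinf = 1.0 / (1.0 + np.exp((V + 58.3) / 6.7))
    ninf = 1.0 / (1.0 + np.exp(-(V + 12.4) / 6.8))
    pinf = (1.0 + np.exp(-(V + 41.4) / 26.6)) ** -4
    qinf = 1.0 / (1.0 + np.exp((V + 78.5) / 6.0))
    s = P[_iTSC]
    tm = s * P[_iTAUM]
    th = s * (P[_iTHF] + P[_iTHA] / (1.0 + np.exp((V + 60.0) / 12.0)))
    tn = s * ((0.087 + 11.4 / (1.0 + np.exp((V + 14.6) / 8.6)))
              * (0.087 + 11.4 / (1.0 + np.exp(-(V - 1.3) / 18.7))))
    tp = s * P[_iTAUP]
    if P[_iTQMODE] > 0.5:
        tq_raw = P[_iTQC]
    else:
        tq_raw = P[_iK] * (V + 105.0)
    tq = s * max(tq_raw, P[_iTAUQF])
    return minf, hinf, ninf, pinf, qinf, tm, th, tn, tp, tq


@njit(cache=True)
def _deriv(P, y, I_pA, gvals, Esyn, instant_m, frozen_q):
    V, m, h, n, p, q = y[0], y[1], y[2], y[3], y[4], y[5]
    minf, hinf, ninf, pinf, qinf, tm, th, tn, tp, tq = _gates_inf_tau(P, V)
    if instant_m:
        m = minf
    conv = 1e-6 / P[_iAREA]  # pA -> µA/cm^2 and nS -> mS/cm^2
    I_ion = (P[_iGL] * (V - P[_iEL])
             + P[_iGKV3] * n * n * (V - P[_iEK])
             + P[_iGKV1] * p * q * (V - P[_iEK])
             + P[_iGNA] * m * m * m * h * (V - P[_iENA]))
    I_syn = 0.0
    for k in range(gvals.size):
        I_syn += gvals[k] * conv * (V - Esyn[k])
    d = np.empty(6)
    d[0] = (I_pA * conv - I_ion - I_syn) / P[_iCM]
    d[1] = 0.0 if instant_m else (minf - m) / tm
    d[2] = (hinf - h) / th
    d[3] = (ninf - n) / tn
    d[4] = (pinf - p) / tp
    d[5] = 0.0 if frozen_q else (qinf - q) / tq
    return d


@njit(cache=True)
def _run(P, I, gsyn, Esyn, dt, y0, method, instant_m, frozen_q):
    n_steps = I.size - 1
    Y = np.empty((n_steps + 1, 6))
    y = y0.copy()
    if instant_m:
        y[1] = 1.0 / (1.0 + np.exp(-(y[0] - P[_iVH]) / 11.5))
    Y[0] = y
    K = Esyn.size
    g_i = np.empty(K)
    g_mid = np.empty(K)
    g_ip1 = np.empty(K)
    for i in range(n_steps):
        for k in range(K):
            g_i[k] = gsyn[k, i]
            g_ip1[k] = gsyn[k, i + 1]
            g_mid[k] = 0.5 * (g_i[k] + g_ip1[k])
        if method == 0:  # RK4
            I_mid = 0.5 * (I[i] + I[i + 1])
            k1 = _deriv(P, y, I[i], g_i, Esyn, instant_m, frozen_q)
            k2 = _deriv(P, y + 0.5 * dt * k1, I_mid, g_mid, Esyn,
                        instant_m, frozen_q)
            k3 = _deriv(P, y + 0.5 * dt * k2, I_mid, g_mid, Esyn,
                        instant_m, frozen_q)
            k4 = _deriv(P, y + dt * k3, I[i + 1], g_ip1, Esyn,
                        instant_m, frozen_q)
            y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        elif method == 1:  # forward Euler (stochastic runs)
            y = y + dt * _deriv(P, y, I[i], g_i, Esyn, instant_m, frozen_q)
        else:  # exponential Euler: Euler on V, Rush-Larsen on gates
            V = y[0]
            d = _deriv(P, y, I[i], g_i, Esyn, instant_m, frozen_q)
            (minf, hinf, ninf, pinf, qinf,
             tm, th, tn, tp, tq) = _gates_inf_tau(P, V)
            y[0] = V + dt * d[0]
            if not instant_m:
                y[1] = minf + (y[1] - minf) * np.exp(-dt / tm)
            y[2] = hinf + (y[2] - hinf) * np.exp(-dt / th)
            y[3] = ninf + (y[3] - ninf) * np.exp(-dt / tn)
            y[4] = pinf + (y[4] - pinf) * np.exp(-dt / tp)
            if not frozen_q:
                y[5] = qinf + (y[5] - qinf) * np.exp(-dt / tq)
        if instant_m:
            y[1] = 1.0 / (1.0 + np.exp(-(y[0] - P[_iVH]) / 11.5))
        ok = np.isfinite(y[0]) and abs(y[0]) < 200.0
        for j in range(1, 6):
            ok = ok and np.isfinite(y[j])
        Y[i + 1] = y
        if not ok:
            return Y[: i + 2], i + 1
    return Y, -1


def resting_state(params: PVINParameters, I_app_pA: float = 0.0,
                  v_lo: float = -110.0, v_hi: float = -20.0) -> np.ndarray:
    """Most hyperpolarized full-system equilibrium [V, m, h, n, p, q].

    All gates (including q) sit on their steady-state curves and the
    total membrane current vanishes.
    """
    from scipy.optimize import brentq

    p = params

    def balance(V):
        g = model_core.steady_gates(V, p)
        dens = model_core._ionic_densities(V, g["m"], g["h"], g["n"],
                                           g["p"], g["q"], p)
        return I_app_pA * p.pA_to_uA_per_cm2 - sum(dens)

    grid = np.linspace(v_lo, v_hi, 400)
    vals = np.array([balance(v) for v in grid])
    sign_changes = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if sign_changes.size == 0:
        raise RuntimeError(
            f"no full-system equilibrium in [{v_lo}, {v_hi}] mV "
            f"at I_app = {I_app_pA} pA")
    i = sign_changes[0]
    V = brentq(balance, grid[i], grid[i + 1], xtol=1e-12)
    g = model_core.steady_gates(V, p)
    return np.array([V, g["m"], g["h"], g["n"], g["p"], g["q"]])


@dataclass
class SimulationResult:
    """Time grid, state traces, stimulus, spike times and metadata."""

    t: np.ndarray                 # ms, shape (N+1,)
    y: np.ndarray                 # shape (N+1, 6): V, m, h, n, p, q
    I_app: np.ndarray             # pA, noise included
    spike_times: np.ndarray       # ms
    dt: float
    params: PVINParameters
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def V(self) -> np.ndarray:
        return self.y[:, 0]

    @property
    def q(self) -> np.ndarray:
        return self.y[:, 5]

    def gate(self, name: str) -> np.ndarray:
        return self.y[:, 1 + model_core.GATES.index(name)]

    def isis(self) -> np.ndarray:
        return np.diff(self.spike_times)

    def current_breakdown(self) -> dict:
        """Per-current traces in pA (whole cell)."""
        p = self.params
        V, m, h, n, pg, q = (self.y[:, i] for i in range(6))
        dens = model_core._ionic_densities(V, m, h, n, pg, q, p)
        to_pA = p.area * 1e6
        names = ("I_leak", "I_Kv3", "I_Kv1", "I_Na")
        out = {k: d * to_pA for k, d in zip(names, dens)}
        out["I_app"] = self.I_app
        return out

    def to_frame(self):
        import pandas as pd

        cols = {"time_ms": self.t, "V_mV": self.V}
        for i, g in enumerate(model_core.GATES, start=1):
            cols[g] = self.y[:, i]
        cols["I_app_pA"] = self.I_app
        return pd.DataFrame(cols)

    def export_csv(self, path, every: int = 1) -> None:
        """Write the trace (decimated by ``every``) plus a sidecar
        ``<path>.meta.json`` and ``<path>.spikes.csv``."""
        import json
        from pathlib import Path

        path = Path(path)
        self.to_frame().iloc[::every].to_csv(path, index=False)
        np.savetxt(path.with_suffix(".spikes.csv"), self.spike_times,
                   header="spike_time_ms", comments="", fmt="%.6f")
        meta = {"dt_ms": self.dt, "seed": self.seed,
                "params_digest": self.params.digest(),
                "params_name": self.params.name, **self.metadata}
        path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))


def detect_spikes(t: np.ndarray, V: np.ndarray, threshold_mV: float = 0.0,
                  refractory_ms: float = 1.0) -> np.ndarray:
    """Spike times from upward threshold crossings with a lockout.

    The reported time is the local voltage maximum within one
    refractory period of the crossing.
    """
    t = np.asarray(t, float)
    V = np.asarray(V, float)
    if t.size != V.size:
        raise ValueError("t and V must have equal length")
    above = V >= threshold_mV
    idx = np.nonzero(above[1:] & ~above[:-1])[0] + 1
    if idx.size == 0:
        return np.empty(0)
    dt_grid = t[1] - t[0]
    w = max(1, int(round(refractory_ms / dt_grid)))
    times = []
    last = -np.inf
    for i in idx:
        if t[i] - last < refractory_ms:
            continue
        j = i + int(np.argmax(V[i: i + w + 1]))
        times.append(t[j])
        last = t[i]
    return np.asarray(times)


def integrate(params: PVINParameters, protocol: StimulusProtocol,
              dt: float | None = None, duration: float | None = None,
              seed: int | None = None, method: str | None = None,
              instant_m: bool = True, frozen_q: float | None = None,
              y0: np.ndarray | None = None,
              spike_threshold_mV: float = 0.0,
              refractory_ms: float = 1.0) -> SimulationResult:
    """Integrate a model under a stimulus protocol.

    Defaults: instantaneous Na activation (m = m_inf) with RK4 at
    dt = 0.025 ms for deterministic protocols, forward Euler at the
    same step for noisy ones.  With ``instant_m=False`` the stiff m
    gate is integrated by exponential Euler at dt = 0.005 ms.

    Raises ``RuntimeError`` with the offending time if the state
    leaves the finite/plausible range.
    """
    noisy = protocol.noise is not None and protocol.noise.sigma_pA > 0
    if method is None:
        if not instant_m:
            method = "exp_euler"
        else:
            method = "euler" if noisy else "rk4"
    if dt is None:
        dt = 0.025 if instant_m else 0.005
    t, I, gsyn, Esyn = protocol.sample(dt, duration_ms=duration, seed=seed)
    if y0 is None:
        y0 = resting_state(params)
    y0 = np.asarray(y0, dtype=float)
    if frozen_q is not None:
        y0 = y0.copy()
        y0[5] = frozen_q
    Y, status = _run(params.as_vector(), I, np.ascontiguousarray(gsyn),
                     Esyn, dt, y0, _METHODS[method],
                     instant_m, frozen_q is not None)
    if status >= 0:
        raise RuntimeError(
            f"integration diverged at t = {status * dt:.3f} ms "
            f"(V = {Y[-1, 0]:.3g} mV)")
    spikes = detect_spikes(t, Y[:, 0], spike_threshold_mV, refractory_ms)
    return SimulationResult(
        t=t, y=Y, I_app=I, spike_times=spikes, dt=dt, params=params,
        seed=seed, metadata={"method": method, "instant_m": instant_m,
                             "frozen_q": frozen_q})


def fi_curve(params: PVINParameters, I_values, duration: float = 2000.0,
             analysis_start: float = 500.0, dt: float = 0.025,
             sustained_tail_ms: float = 500.0):
    """Frequency/current relation from constant current steps.

    For each current the model runs for ``duration`` ms from rest.
    The sustained frequency is the mean rate over spikes after
    ``analysis_start``; a response whose last spike precedes the final
    ``sustained_tail_ms`` of the record counts as transient only
    (sustained frequency 0, spike count reported).  The returned
    DataFrame carries the onset point of sustained firing (the f/I
    discontinuity) in ``df.attrs``.
    """
    import pandas as pd

    from .stimulus import step_protocol

    rows = []
    y0 = resting_state(params)
    for I in I_values:
        res = integrate(params, step_protocol(float(I), duration),
                        dt=dt, y0=y0)
        st = res.spike_times
        in_win = st[st >= analysis_start]
        sustained = (st.size > 0 and st[-1] >= duration - sustained_tail_ms
                     and in_win.size >= 2)
        if sustained:
            f = 1000.0 * (in_win.size - 1) / (in_win[-1] - in_win[0])
        else:
            f = 0.0
        rows.append({"I_pA": float(I), "f_Hz": f,
                     "n_spikes": int(st.size), "sustained": bool(sustained)})
    df = pd.DataFrame(rows)
    onset = df[df.sustained]
    if len(onset):
        df.attrs["onset_I_pA"] = float(onset.I_pA.iloc[0])
        df.attrs["onset_f_Hz"] = float(onset.f_Hz.iloc[0])
    else:
        df.attrs["onset_I_pA"] = np.nan
        df.attrs["onset_f_Hz"] = np.nan
    return df
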