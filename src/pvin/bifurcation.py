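"""Fast/slow bifurcation analysis of the PV-IN model.

The slow Kv1 inactivation gate ``q`` is frozen as a bifurcation
parameter and the remaining (fast) subsystem is analysed:

* equilibrium continuation by a secant-predictor / Newton-corrector
  pseudo-arclength scheme with eigenvalues attached at every point;
* Hopf detection by bisection on the sign change of the leading
  complex eigenvalue pair, with criticality labelled from the
  stability of the emanating cycle;
* stable limit cycles by long integration from a spiking initial
  condition; the unstable cycle by bisection of the basin boundary
  along a ray in state space;
* the saddle-node of periodics (SNPO) as the largest ``q`` retaining
  a stable cycle;
* the firing-regime classification over the (g_Kv1, I_app) plane.

The same machinery continues equilibria in ``I_app`` instead of ``q``
(used for models whose bistability lives directly in the applied
current).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from . import model_core as mc
from .integrate import integrate
from .params import PVINParameters
from .stimulus import step_protocol

__all__ = [
    "EquilibriumBranch", "HopfPoint", "LimitCycleBranch", "RegimeGrid",
    "find_equilibrium", "continue_equilibria", "detect_hopf",
    "stable_limit_cycle", "unstable_limit_cycle", "limit_cycle_branch",
    "detect_snpo",
    "classify_trace", "regime_scan", "q_nullcline", "fast_jacobian",
]

REGIMES = ("quiescent", "transient", "elliptical_bursting", "tonic")


# ----------------------------------------------------------------------
# Equilibria of the fast subsystem
# ----------------------------------------------------------------------

def _balance(params: PVINParameters, V: float, q: float,
             I_app_pA: float) -> float:
    """Total membrane current (µA/cm², applied minus ionic) with every
    fast gate at its steady state and q frozen."""
    g = mc.steady_gates(V, params)
    dens = mc._ionic_densities(V, g["m"], g["h"], g["n"], g["p"], q, params)
    return I_app_pA * params.pA_to_uA_per_cm2 - sum(dens)


def find_equilibrium(params: PVINParameters, q: float, I_app_pA: float,
                     v_guess: float | None = None,
                     v_window: float = 8.0) -> np.ndarray:
    """Equilibrium state [V, m, h, n, p, q] of the frozen-q subsystem.

    Solves the scalar current balance in V (every fast gate slaved to
    its steady-state curve at an equilibrium).  With ``v_guess`` the
    root nearest the guess is returned; otherwise the most depolarized
    root.  Residual of the full right-hand side is below 1e-10.
    """
    f = lambda V: _balance(params, V, q, I_app_pA)
    if v_guess is not None:
        lo, hi = v_guess - v_window, v_guess + v_window
        if f(lo) * f(hi) > 0:
            raise RuntimeError(
                f"no equilibrium near V = {v_guess} mV (q={q}, "
                f"I={I_app_pA} pA); residuals {f(lo):.3g}, {f(hi):.3g}")
        V = brentq(f, lo, hi, xtol=1e-13)
    else:
        grid = np.linspace(-120.0, 20.0, 800)
        vals = np.array([f(v) for v in grid])
        idx = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
        if idx.size == 0:
            raise RuntimeError(
                f"no frozen-q equilibrium at q={q}, I={I_app_pA} pA")
        V = brentq(f, grid[idx[-1]], grid[idx[-1] + 1], xtol=1e-13)
    g = mc.steady_gates(V, params)
    state = np.array([V, g["m"], g["h"], g["n"], g["p"], q])
    res = mc.rhs(state, I_app_pA, params, frozen_q=q)
    if np.linalg.norm(res) > 1e-10:
        raise RuntimeError(f"equilibrium residual {np.linalg.norm(res):.2e}")
    return state


def fast_jacobian(params: PVINParameters, state: np.ndarray,
                  I_app_pA: float, instant_m: bool = True) -> np.ndarray:
    """Jacobian of the frozen-q fast subsystem at a state.

    With ``instant_m`` (the default, matching the integrator) the
    subsystem is (V, h, n, p); otherwise (V, m, h, n, p) including the
    1 µs m gate.
    """
    idx = [0, 2, 3, 4] if instant_m else [0, 1, 2, 3, 4]
    q = state[5]
    n = len(idx)
    J = np.empty((n, n))
    f0 = mc.rhs(state, I_app_pA, params, frozen_q=q, instant_m=instant_m)
    for col, j in enumerate(idx):
        eps = 1e-7 * max(1.0, abs(state[j]))
        sp = state.copy()
        sp[j] += eps
        fp = mc.rhs(sp, I_app_pA, params, frozen_q=q, instant_m=instant_m)
        J[:, col] = (fp[idx] - f0[idx]) / eps
    return J


def _leading_complex_re(eigvals: np.ndarray) -> float:
    """Max real part among complex-conjugate eigenvalue pairs (or the
    overall max real part if no complex pair exists)."""
    cplx = eigvals[np.abs(eigvals.imag) > 1e-9]
    if cplx.size:
        return float(cplx.real.max())
    return float(eigvals.real.max())


@dataclass
class EquilibriumBranch:
    """Continuation output over a scalar parameter (q or I_app)."""

    parameter: str                # "q" or "I_app"
    values: np.ndarray            # parameter values along the branch
    states: np.ndarray            # (n, 6) equilibrium states
    eigvals: np.ndarray           # (n, d) complex Jacobian spectra
    stable: np.ndarray            # (n,) bool

    @property
    def V(self) -> np.ndarray:
        return self.states[:, 0]

    def to_frame(self):
        import pandas as pd

        lead = np.array([ev[np.argsort(ev.real)][-1] for ev in self.eigvals])
        return pd.DataFrame({
            self.parameter: self.values, "V_mV": self.V,
            "stable": self.stable,
            "re_lead": lead.real, "im_lead": lead.imag,
        })


@dataclass
class HopfPoint:
    parameter: str
    value: float                  # parameter at the crossing
    state: np.ndarray             # equilibrium state there
    eig_pair: complex             # crossing eigenvalue (Im > 0)
    criticality: str = "unknown"  # "subcritical" / "supercritical"


def continue_equilibria(params: PVINParameters, I_app_pA: float,
                        param_range: tuple[float, float],
                        parameter: str = "q",
                        frozen_q: float | None = None,
                        n_target: int = 200, instant_m: bool = True,
                        v_start: float | None = None) -> EquilibriumBranch:
    """Trace an equilibrium branch by pseudo-arclength continuation.

    For ``parameter="q"`` the branch of the frozen-q fast subsystem at
    fixed ``I_app_pA`` is continued; for ``parameter="I_app"`` the
    applied current is the bifurcation parameter (``frozen_q`` fixes q,
    or q is slaved to its steady state if None).  Secant predictor,
    Newton corrector on (V, parameter) with an arclength constraint,
    and adaptive step halving on corrector failure.  Eigenvalues of the
    fast Jacobian are attached at every accepted point.
    """
    lam0, lam1 = param_range

    def bal(V, lam):
        if parameter == "q":
            return _balance(params, V, lam, I_app_pA)
        q = (frozen_q if frozen_q is not None
             else mc.gate_steady_state("q", V, params))
        return _balance(params, V, q, lam)

    def eq_state(V, lam):
        if parameter == "q":
            q = lam
            I = I_app_pA
        else:
            q = (frozen_q if frozen_q is not None
                 else mc.gate_steady_state("q", V, params))
            I = lam
        g = mc.steady_gates(V, params)
        st = np.array([V, g["m"], g["h"], g["n"], g["p"], q])
        return st, I

    # starting point
    if parameter == "q":
        st0 = find_equilibrium(params, lam0, I_app_pA, v_guess=v_start)
        V = st0[0]
    else:
        grid = np.linspace(-120.0, 20.0, 800)
        vals = np.array([bal(v, lam0) for v in grid])
        idx = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
        if idx.size == 0:
            raise RuntimeError("no starting equilibrium for continuation")
        V = brentq(lambda v: bal(v, lam0), grid[idx[0]], grid[idx[0] + 1],
                   xtol=1e-13)

    # scaled coordinates u = (V / v_scale, lam / lam_scale) so that the
    # arclength treats both directions comparably
    v_scale = 25.0
    lam_scale = abs(lam1 - lam0)
    h = 1.0 / n_target            # arclength step in scaled units

    def to_u(V, lam):
        return np.array([V / v_scale, lam / lam_scale])

    def from_u(u):
        return u[0] * v_scale, u[1] * lam_scale

    def corrector(u_pred, u_prev, tangent, ds):
        """Newton on [balance; arclength constraint]."""
        u = u_pred.copy()
        for _ in range(25):
            V, lam = from_u(u)
            F = np.array([bal(V, lam),
                          tangent @ (u - u_prev) - ds])
            eps = 1e-8
            J = np.empty((2, 2))
            J[0, 0] = (bal(V + eps * v_scale, lam) - F[0]) / eps
            J[0, 1] = (bal(V, lam + eps * lam_scale) - F[0]) / eps
            J[1, :] = tangent
            try:
                du = np.linalg.solve(J, -F)
            except np.linalg.LinAlgError:
                return None
            u = u + du
            if abs(F[0]) < 1e-11 and np.linalg.norm(du) < 1e-11:
                return u
        return None

    pts = [to_u(V, lam0)]
    # first step: natural continuation in the parameter
    lam_next = lam0 + np.sign(lam1 - lam0) * h * lam_scale
    try:
        V_next = brentq(lambda v: bal(v, lam_next), V - 5.0, V + 5.0,
                        xtol=1e-13)
    except ValueError:
        V_next = V
    pts.append(to_u(V_next, lam_next))

    max_pts = 30 * n_target
    ds = h
    while len(pts) < max_pts:
        tangent = pts[-1] - pts[-2]
        norm = np.linalg.norm(tangent)
        if norm == 0:
            break
        tangent = tangent / norm
        accepted = None
        ds_try = ds
        for _ in range(10):
            u_pred = pts[-1] + tangent * ds_try
            u_new = corrector(u_pred, pts[-1], tangent, ds_try)
            if u_new is not None:
                accepted = u_new
                break
            ds_try *= 0.5
        if accepted is None:
            break
        pts.append(accepted)
        ds = min(h, ds_try * 2.0)
        lam_cur = from_u(accepted)[1]
        lo, hi = sorted((lam0, lam1))
        if not (lo - 1e-9 <= lam_cur <= hi + 1e-9):
            break

    values = np.array([from_u(u)[1] for u in pts])
    pts_V = [from_u(u)[0] for u in pts]
    eig_list, states, stab = [], [], []
    for lam, V in zip(values, pts_V):
        st, I = eq_state(V, lam)
        J = fast_jacobian(params, st, I, instant_m=instant_m)
        ev = np.linalg.eigvals(J)
        eig_list.append(ev)
        states.append(st)
        stab.append(bool(np.all(ev.real < 0)))
    return EquilibriumBranch(
        parameter=parameter, values=values, states=np.array(states),
        eigvals=np.array(eig_list), stable=np.array(stab))


def detect_hopf(branch: EquilibriumBranch, params: PVINParameters,
                I_app_pA: float | None = None,
                instant_m: bool = True,
                classify: bool = False) -> list[HopfPoint]:
    """Hopf points along an equilibrium branch.

    Sign changes of the leading complex-pair real part between
    consecutive branch points are bracketed and refined by bisection in
    the parameter to |Re λ| < 1e-8.  With ``classify=True`` the
    criticality is labelled from the emanating cycle: subcritical if
    a small perturbation on the unstable side grows to a large
    (spiking-amplitude) oscillation.
    """
    def re_at(lam, v_guess):
        if branch.parameter == "q":
            st = find_equilibrium(params, lam, I_app_pA, v_guess=v_guess)
            I = I_app_pA
        else:
            f = lambda V: _balance(
                params, V, mc.gate_steady_state("q", V, params), lam)
            V = brentq(f, v_guess - 6.0, v_guess + 6.0, xtol=1e-13)
            g = mc.steady_gates(V, params)
            st = np.array([V, g["m"], g["h"], g["n"], g["p"], g["q"]])
            I = lam
        ev = np.linalg.eigvals(fast_jacobian(params, st, I,
                                             instant_m=instant_m))
        return _leading_complex_re(ev), st, ev

    res = np.array([_leading_complex_re(ev) for ev in branch.eigvals])
    hopfs = []
    for i in np.nonzero(np.diff(np.sign(res)) != 0)[0]:
        lo, hi = branch.values[i], branch.values[i + 1]
        v_lo, v_hi = branch.V[i], branch.V[i + 1]
        r_lo, _, _ = re_at(lo, v_lo)
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            v_guess = 0.5 * (v_lo + v_hi)
            r_mid, st_mid, ev_mid = re_at(mid, v_guess)
            if abs(r_mid) < 1e-8:
                break
            if np.sign(r_mid) == np.sign(r_lo):
                lo, v_lo, r_lo = mid, st_mid[0], r_mid
            else:
                hi, v_hi = mid, st_mid[0]
        pair = ev_mid[ev_mid.imag > 1e-9]
        pair = pair[np.argmax(pair.real)] if pair.size else ev_mid[0]
        hp = HopfPoint(parameter=branch.parameter, value=float(mid),
                       state=st_mid, eig_pair=complex(pair))
        if classify:
            hp.criticality = _hopf_criticality(params, hp, I_app_pA)
        hopfs.append(hp)
    return hopfs


def _hopf_criticality(params: PVINParameters, hp: HopfPoint,
                      I_app_pA: float | None) -> str:
    """Label a Hopf by the stability of the emanating cycle.

    Just past the Hopf on the unstable side, a small perturbation is
    integrated; if the resulting oscillation saturates at spiking
    amplitude (rather than a small stable cycle) the Hopf is
    subcritical.
    """
    if hp.parameter == "q":
        # the branch is stable for q above the Hopf: probe just below
        q_probe = hp.value * 0.97
        I = I_app_pA
        cyc = stable_limit_cycle(params, q_probe, I,
                                 y0=hp.state + np.array([1.0, 0, 0, 0, 0, 0]))
    else:
        I = hp.value * 1.02
        cyc = stable_limit_cycle(params, None, I, frozen=False,
                                 y0=hp.state + np.array([1.0, 0, 0, 0, 0, 0]))
    if cyc is not None and (cyc["V_max"] - cyc["V_min"]) > 20.0:
        return "subcritical"
    return "supercritical"


# ----------------------------------------------------------------------
# Limit cycles
# ----------------------------------------------------------------------

def stable_limit_cycle(params: PVINParameters, q: float | None,
                       I_app_pA: float, duration: float = 800.0,
                       dt: float = 0.01, settle_frac: float = 0.5,
                       y0: np.ndarray | None = None,
                       frozen: bool = True) -> dict | None:
    """Stable periodic orbit of the frozen-q subsystem, or None.

    Integrates from a spiking initial condition (hyperpolarized, Na
    fully available) and, after discarding the transient, extracts
    V_max, V_min and the period from the spike returns.  Returns None
    if the trajectory converges to the equilibrium instead.
    """
    if y0 is None:
        y0 = np.array([-80.0, 0.0, 0.9, 0.0, 0.0, q if q is not None else 0.0])
    res = integrate(params, step_protocol(I_app_pA, duration), dt=dt,
                    frozen_q=q if frozen else None, y0=y0)
    t0 = duration * settle_frac
    sel = res.t >= t0
    st = res.spike_times
    st = st[st >= t0]
    Vw = res.V[sel]
    if st.size < 3 or st[-1] < duration - 3.0 * np.median(np.diff(st)):
        # check convergence to equilibrium
        tail = res.V[res.t >= duration - 50.0]
        if tail.max() - tail.min() < 1.0:
            return None
        return None
    period = float(np.mean(np.diff(st)))
    return {"q": q, "I_app_pA": I_app_pA, "V_max": float(Vw.max()),
            "V_min": float(Vw.min()), "period_ms": period, "stable": True}


def unstable_limit_cycle(params: PVINParameters, q: float,
                         I_app_pA: float, tol_mV: float = 0.05,
                         horizon_ms: float = 400.0,
                         direction: int = +1) -> dict:
    """Amplitude estimate of the unstable cycle by basin-boundary
    bisection.

    Along a ray in V from the stable equilibrium (gates held at their
    equilibrium values), initial conditions inside the unstable cycle
    decay back to the equilibrium while those outside spiral out to the
    spiking cycle.  The boundary (≈ the unstable cycle's V extreme) is
    bisected to ``tol_mV``.
    """
    eq = find_equilibrium(params, q, I_app_pA)
    cyc = stable_limit_cycle(params, q, I_app_pA)
    if cyc is None:
        return {"q": q, "I_app_pA": I_app_pA, "exists": False,
                "reason": "no bistability: stable cycle absent"}
    ev = np.linalg.eigvals(fast_jacobian(params, eq, I_app_pA))
    if not np.all(ev.real < 0):
        return {"q": q, "I_app_pA": I_app_pA, "exists": False,
                "reason": "no bistability: equilibrium unstable"}

    span = (cyc["V_max"] - eq[0]) if direction > 0 else (eq[0] - cyc["V_min"])

    def escapes(a):
        y0 = eq.copy()
        y0[0] = eq[0] + direction * a
        res = integrate(params, step_protocol(I_app_pA, horizon_ms),
                        frozen_q=q, y0=y0)
        return res.spike_times.size > 0

    lo, hi = 0.0, abs(span)
    if not escapes(hi):
        hi = abs(span) * 1.5
        if not escapes(hi):
            return {"q": q, "I_app_pA": I_app_pA, "exists": False,
                    "reason": "no escape along ray"}
    while hi - lo > tol_mV:
        mid = 0.5 * (lo + hi)
        if escapes(mid):
            hi = mid
        else:
            lo = mid
    amp = 0.5 * (lo + hi)
    return {"q": q, "I_app_pA": I_app_pA, "exists": True,
            "V_eq": float(eq[0]), "amplitude_mV": float(amp),
            "V_extreme": float(eq[0] + direction * amp),
            "bracket_mV": (float(lo), float(hi))}


@dataclass
class LimitCycleBranch:
    """Sampled limit-cycle branch over frozen q at fixed I_app.

    Stable points come from forward-time convergence
    (:func:`stable_limit_cycle`); unstable points from the
    basin-boundary construction (:func:`unstable_limit_cycle`), which
    yields the V maximum of the unstable cycle only.
    """

    I_app_pA: float
    q: np.ndarray
    V_max: np.ndarray
    V_min: np.ndarray              # NaN on the unstable branch
    period_ms: np.ndarray          # NaN on the unstable branch
    stable: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"q": self.q, "V_max": self.V_max,
                             "V_min": self.V_min,
                             "period_ms": self.period_ms,
                             "stable": self.stable})


def limit_cycle_branch(params: PVINParameters, I_app_pA: float,
                       q_stable, q_unstable=()) -> LimitCycleBranch:
    """Sample stable and unstable cycle branches at the given q values
    (points where no cycle of the requested kind exists are skipped)."""
    rows = []
    for q in np.asarray(q_stable, float):
        cyc = stable_limit_cycle(params, float(q), I_app_pA)
        if cyc is not None:
            rows.append((q, cyc["V_max"], cyc["V_min"],
                         cyc["period_ms"], True))
    for q in np.asarray(q_unstable, float):
        u = unstable_limit_cycle(params, float(q), I_app_pA)
        if u.get("exists"):
            rows.append((q, u["V_extreme"], np.nan, np.nan, False))
    if rows:
        qv, vmax, vmin, per, stab = map(np.array, zip(*rows))
    else:
        qv = vmax = vmin = per = np.empty(0)
        stab = np.empty(0, dtype=bool)
    return LimitCycleBranch(I_app_pA=I_app_pA, q=qv, V_max=vmax,
                            V_min=vmin, period_ms=per,
                            stable=stab.astype(bool))


def detect_snpo(params: PVINParameters, I_app_pA: float,
                q_range: tuple[float, float] = (0.05, 0.7),
                tol: float = 1e-3, duration: float = 600.0,
                dt: float = 0.01) -> float | None:
    """Largest frozen q supporting a stable limit cycle (the SNPO),
    refined by bisection to ``tol``."""
    def has_cycle(q):
        return stable_limit_cycle(params, q, I_app_pA, duration=duration,
                                  dt=dt) is not None

    lo, hi = q_range
    if not has_cycle(lo):
        return None
    while has_cycle(hi):
        hi += 0.2
        if hi > 1.5:
            return None
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if has_cycle(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def q_nullcline(V_grid, params: PVINParameters | None = None) -> np.ndarray:
    """The q nullcline: q_inf(V), the steady Kv1 availability at each
    membrane potential.  Below it q grows, above it q decays."""
    return mc.gate_steady_state("q", np.asarray(V_grid, float),
                                params or PVINParameters())


# ----------------------------------------------------------------------
# Firing-regime classification
# ----------------------------------------------------------------------

@dataclass
class RegimeGrid:
    g_Kv1: np.ndarray             # mS/cm²
    I_app: np.ndarray             # pA
    labels: np.ndarray            # (len(g), len(I)) of REGIMES strings
    ambiguous: list = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.labels, index=pd.Index(self.g_Kv1,
                                                        name="g_Kv1"),
                            columns=pd.Index(self.I_app, name="I_app_pA"))


def classify_trace(spike_times: np.ndarray, duration_ms: float,
                   analysis_start_ms: float = 500.0,
                   quiet_tail_ms: float = 1000.0,
                   gap_factor: float = 5.0,
                   min_gaps_for_burst: int = 2) -> str:
    """Label a fixed-duration response as quiescent / transient /
    elliptical_bursting / tonic.

    transient: at least one spike but none in the final
    ``quiet_tail_ms`` and no resumption after a silent gap;
    elliptical bursting: at least ``min_gaps_for_burst`` silent gaps
    exceeding ``gap_factor`` times the median ISI separating spike
    epochs — the silent stretch after the last spike counts as a gap,
    so a slow burst cycle only partially covered by the record is
    still recognised; tonic: sustained firing without such gaps.  A
    trace with a single internal gap and firing through the end of the
    record is ambiguous between delayed tonic and a burst period
    longer than the record; the tie-break labels it tonic.
    """
    st = np.asarray(spike_times, float)
    if st.size == 0:
        return "quiescent"
    isis = np.diff(st)
    if isis.size >= 2:
        med = np.median(isis)
        gap_thr = gap_factor * med
    else:
        gap_thr = quiet_tail_ms
    internal_gaps = int(np.sum(isis > gap_thr)) if isis.size else 0
    trailing = duration_ms - st[-1]
    n_gaps = internal_gaps + (1 if trailing > max(gap_thr, 50.0) else 0)
    if internal_gaps >= 1 and n_gaps >= min_gaps_for_burst:
        return "elliptical_bursting"
    if st[-1] < duration_ms - quiet_tail_ms:
        return "transient"
    return "tonic"


def regime_scan(params: PVINParameters, g_values=None, I_values=None,
                duration_ms: float = 3000.0, dt: float = 0.025,
                **classify_kw) -> RegimeGrid:
    """Classify the firing regime over a (g_Kv1, I_app) grid.

    Defaults reproduce the published sweep: I_app from 0 to 1000 pA in
    30 pA increments and g_Kv1 from 0 to 10 mS/cm² in 1 mS/cm² steps,
    each cell simulated for 3 s from rest.
    """
    g_values = np.arange(0.0, 10.0 + 1e-9, 1.0) if g_values is None \
        else np.asarray(g_values, float)
    I_values = np.arange(0.0, 1000.0 + 1e-9, 30.0) if I_values is None \
        else np.asarray(I_values, float)
    labels = np.empty((g_values.size, I_values.size), dtype=object)
    ambiguous = []
    for i, g in enumerate(g_values):
        p = params.replace(g_Kv1=float(g))
        y0 = None
        for j, I in enumerate(I_values):
            if y0 is None:
                from .integrate import resting_state

                y0 = resting_state(p)
            res = integrate(p, step_protocol(float(I), duration_ms),
                            dt=dt, y0=y0)
            lab = classify_trace(res.spike_times, duration_ms, **classify_kw)
            labels[i, j] = lab
    return RegimeGrid(g_Kv1=g_values, I_app=I_values, labels=labels,
                      ambiguous=ambiguous)
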