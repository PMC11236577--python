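"""Stimulus protocols: current steps, ramps, noise, synaptic conductances.

A :class:`StimulusProtocol` is an ordered list of current segments that
tile a finite duration, an optional zero-mean Gaussian current-noise
overlay, and a list of biexponential synaptic conductance events.  The
protocol is sampled onto a uniform time grid before integration, so a
(protocol, dt, seed) triple maps to exactly one realization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConstantCurrent", "RampCurrent", "NoiseSpec", "SynapticEvent",
    "StimulusProtocol", "mock_ipsp_protocol", "step_protocol",
    "biexp_conductance",
]


@dataclass(frozen=True)
class ConstantCurrent:
    amplitude_pA: float
    duration_ms: float


@dataclass(frozen=True)
class RampCurrent:
    start_pA: float
    end_pA: float
    duration_ms: float


@dataclass(frozen=True)
class NoiseSpec:
    """Zero-mean Gaussian current noise, sampled independently per step."""

    sigma_pA: float
    t_start_ms: float = 0.0
    t_end_ms: float = np.inf

    def __post_init__(self):
        if self.sigma_pA < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.t_end_ms <= self.t_start_ms:
            raise ValueError("noise window is empty or reversed")


@dataclass(frozen=True)
class SynapticEvent:
    """Biexponential conductance transient g(t) with unit-normalized peak."""

    onset_ms: float
    g_peak_nS: float
    E_rev_mV: float
    tau_rise_ms: float = 0.5
    tau_decay_ms: float = 1.0

    def __post_init__(self):
        if self.g_peak_nS < 0:
            raise ValueError("peak conductance must be >= 0")
        if self.tau_rise_ms <= 0 or self.tau_decay_ms <= 0:
            raise ValueError("synaptic time constants must be > 0")
        if self.tau_rise_ms >= self.tau_decay_ms:
            import warnings

            warnings.warn("synaptic rise time >= decay time", stacklevel=2)


def biexp_conductance(t_ms, event: SynapticEvent) -> np.ndarray:
    """Sample g(t) in nS; the waveform peak equals ``g_peak_nS`` exactly."""
    t = np.asarray(t_ms, dtype=float) - event.onset_ms
    tr, td = event.tau_rise_ms, event.tau_decay_ms
    if tr == td:  # limit case: alpha function
        g = (t / tr) * np.exp(1.0 - t / tr)
    else:
        t_peak = tr * td / (td - tr) * np.log(td / tr)
        norm = np.exp(-t_peak / td) - np.exp(-t_peak / tr)
        g = (np.exp(-t / td) - np.exp(-t / tr)) / norm
    g = np.where(t >= 0.0, g, 0.0)
    return event.g_peak_nS * g


@dataclass
class StimulusProtocol:
    """Composable applied-current waveform plus noise and synapses."""

    segments: list = field(default_factory=list)
    noise: NoiseSpec | None = None
    synapses: list = field(default_factory=list)

    @property
    def duration_ms(self) -> float:
        return sum(s.duration_ms for s in self.segments)

    def _validate(self) -> None:
        for s in self.segments:
            if s.duration_ms <= 0:
                raise ValueError(f"segment with nonpositive duration: {s}")

    def current_waveform(self, t_ms) -> np.ndarray:
        """Deterministic (noise-free) applied current I(t) in pA."""
        self._validate()
        t = np.asarray(t_ms, dtype=float)
        out = np.zeros_like(t)
        t0 = 0.0
        for seg in self.segments:
            t1 = t0 + seg.duration_ms
            mask = (t >= t0) & (t < t1)
            if isinstance(seg, ConstantCurrent):
                out[mask] = seg.amplitude_pA
            elif isinstance(seg, RampCurrent):
                frac = (t[mask] - t0) / seg.duration_ms
                out[mask] = seg.start_pA + frac * (seg.end_pA - seg.start_pA)
            else:
                raise TypeError(f"unknown segment type {type(seg)}")
            t0 = t1
        if self.segments:
            last = self.segments[-1]
            level = (last.amplitude_pA if isinstance(last, ConstantCurrent)
                     else last.end_pA)
            out[t >= t0] = level
        return out

    def sample(self, dt_ms: float, duration_ms: float | None = None,
               seed: int | None = None):
        """Sample the protocol on a uniform grid.

        Returns ``(t, I, g_syn, E_syn)`` where ``t`` has N+1 points,
        ``I`` is the applied current in pA (noise included), ``g_syn``
        is a (n_events, N+1) array of conductances in nS and ``E_syn``
        the per-event reversal potentials in mV.
        """
        dur = self.duration_ms if duration_ms is None else duration_ms
        if dur <= 0:
            raise ValueError("protocol duration must be > 0")
        n = int(round(dur / dt_ms))
        t = np.arange(n + 1) * dt_ms
        I = self.current_waveform(t)
        if self.noise is not None and self.noise.sigma_pA > 0:
            if seed is None:
                raise ValueError("a seed is required for a noisy protocol")
            rng = np.random.default_rng(seed)
            eta = rng.normal(0.0, self.noise.sigma_pA, size=t.shape)
            window = (t >= self.noise.t_start_ms) & (t < self.noise.t_end_ms)
            I = I + np.where(window, eta, 0.0)
        if self.synapses:
            g_syn = np.stack([biexp_conductance(t, ev) for ev in self.synapses])
            E_syn = np.array([ev.E_rev_mV for ev in self.synapses])
        else:
            g_syn = np.zeros((0, t.size))
            E_syn = np.zeros(0)
        return t, I, g_syn, E_syn


def step_protocol(amplitude_pA: float, duration_ms: float,
                  delay_ms: float = 0.0, **kw) -> StimulusProtocol:
    """Constant current step, optionally after a zero-current delay."""
    segs = []
    if delay_ms > 0:
        segs.append(ConstantCurrent(0.0, delay_ms))
    segs.append(ConstantCurrent(amplitude_pA, duration_ms))
    return StimulusProtocol(segments=segs, **kw)


def mock_ipsp_protocol(hold_pA: float, amplitude_pA: float, ramp_ms: float,
                       onset_ms: float, post_ms: float = 2000.0,
                       allow_negative: bool = False, **kw) -> StimulusProtocol:
    """Holding current with a mock IPSP: an instantaneous drop of
    ``amplitude_pA`` at ``onset_ms`` followed by a linear ramp back to
    the holding level over ``ramp_ms``.

    The canonical protocol holds at 450 pA, drops to 350 pA and ramps
    back over 200 ms.
    """
    if ramp_ms <= 0:
        raise ValueError("ramp duration must be > 0")
    low = hold_pA - amplitude_pA
    if low < 0 and not allow_negative:
        raise ValueError(
            f"mock IPSP would drive the current negative ({low} pA); "
            "pass allow_negative=True to permit this"
        )
    segs = [
        ConstantCurrent(hold_pA, onset_ms),
        RampCurrent(low, hold_pA, ramp_ms),
        ConstantCurrent(hold_pA, post_ms),
    ]
    return StimulusProtocol(segments=segs, **kw)
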