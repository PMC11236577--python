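"""Seeded surrogate data generators.

Surrogate voltage traces with known ground truth (spike times, stutter
gaps) exercise the trace analyzers — spike detection, the minimum
sustained-frequency rule, interruption timing — without running the
biophysical model.  Stimulus waveform sampling itself lives on
:class:`pvin.stimulus.StimulusProtocol`; :func:`gen_stimulus` is the
functional wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stimulus import StimulusProtocol

__all__ = ["SurrogateTraceSpec", "gen_surrogate_trace", "gen_stimulus"]


def gen_stimulus(protocol: StimulusProtocol, dt_ms: float,
                 seed: int | None = None, duration_ms: float | None = None):
    """Sample a stimulus protocol onto a uniform grid (deterministic
    per seed).  Returns (t, I_pA, g_syn_nS, E_syn_mV)."""
    return protocol.sample(dt_ms, duration_ms=duration_ms, seed=seed)


@dataclass(frozen=True)
class SurrogateTraceSpec:
    """Stuttering-trace generator settings.

    Spikes fire regularly at ``rate_Hz`` within bursts of
    ``burst_ms``; bursts are separated by silent gaps of ``gap_ms``
    (``gap_ms = 0`` gives an uninterrupted regular train).  Spikes are
    stereotyped triangular pulses — threshold-crossing detection does
    not depend on the waveform shape.
    """

    rate_Hz: float = 40.0
    burst_ms: float = 500.0
    gap_ms: float = 0.0
    n_bursts: int = 1
    spike_amp_mV: float = 95.0      # peak relative to baseline
    spike_base_ms: float = 2.0
    baseline_mV: float = -65.0
    noise_sd_mV: float = 0.0
    dt_ms: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.rate_Hz <= 0:
            raise ValueError("rate must be > 0")
        if self.gap_ms < 0:
            raise ValueError("gap must be >= 0")


def gen_surrogate_trace(spec: SurrogateTraceSpec):
    """Generate (t, V, true_spike_times, true_gaps).

    ``true_gaps`` is a list of (gap_start_ms, gap_end_ms) for the
    silent epochs between bursts; gap_start marks the last spike of the
    preceding burst (the "offset" an interruption would be measured
    from).
    """
    isi = 1000.0 / spec.rate_Hz
    spikes = []
    gaps = []
    t0 = 10.0
    for b in range(spec.n_bursts):
        n_sp = max(1, int(round(spec.burst_ms / isi)))
        burst = t0 + np.arange(n_sp) * isi
        spikes.extend(burst)
        if b < spec.n_bursts - 1 and spec.gap_ms > 0:
            gaps.append((burst[-1], burst[-1] + spec.gap_ms + isi))
            t0 = burst[-1] + spec.gap_ms + isi
        else:
            t0 = burst[-1] + isi
    spikes = np.array(spikes)
    total = spikes[-1] + 50.0
    t = np.arange(0.0, total, spec.dt_ms)
    V = np.full_like(t, spec.baseline_mV)
    half = spec.spike_base_ms / 2.0
    for s in spikes:
        mask = np.abs(t - s) < half
        V[mask] += spec.spike_amp_mV * (1.0 - np.abs(t[mask] - s) / half)
    if spec.noise_sd_mV > 0:
        rng = np.random.default_rng(spec.seed)
        V = V + rng.normal(0.0, spec.noise_sd_mV, size=t.shape)
    return t, V, spikes, gaps
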