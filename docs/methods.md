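# Methods

## Model equations and units

Single compartment.  Specific capacitance C_M = 1 µF/cm²; membrane
area A = 5.09×10⁻⁵ cm², fixed so the whole-cell capacitance is
50.9 pF.  Whole-cell inputs (pA, nS) are converted to densities
through A, so 1 µA/cm² ↔ 50.9 pA.

    C_M dV/dt = I_app − I_leak − I_Kv3 − I_Kv1 − I_Na
    I_leak = g_L (V − E_L)                     g_L   = 0.25 mS/cm²
    I_Kv3  = g_Kv3 n² (V − E_K)                g_Kv3 = 223 mS/cm²
    I_Kv1  = g_Kv1 p q (V − E_K)               g_Kv1 = 5 mS/cm²
    I_Na   = g_Na m³ h (V − E_Na)              g_Na  = 112.5 mS/cm²
    E_K = −90 mV, E_Na = 50 mV, E_L = −70 mV (calibrated, below)

Gating, dx/dt = (x_∞ − x)/τ_x:

    m_∞ = 1/(1+exp(−(V−V_h)/11.5)),  V_h = −22 mV,  τ_m = 0.001 ms
    h_∞ = 1/(1+exp((V+58.3)/6.7)),   τ_h = 0.5 + 14/(1+exp((V+60)/12)) ms
    n_∞ = 1/(1+exp(−(V+12.4)/6.8)),
    τ_n = (0.087+11.4/(1+exp((V+14.6)/8.6)))
        × (0.087+11.4/(1+exp(−(V−1.3)/18.7))) ms
    p_∞ = (1+exp(−(V+41.4)/26.6))⁻⁴,  τ_p = 0.448 ms
    q_∞ = 1/(1+exp((V+78.5)/6)),      τ_q = max(k(V+105), 0.1) ms, k = 7.5

q is the slow Kv1 inactivation (availability) gate: τ_q is ~500 ms at
the depolarized potentials visited between spikes and ~100–150 ms in
the spike afterhyperpolarization, so q integrates the firing history.
Temperature enters through a Q10 of 2 referred to 23 °C: every τ is
divided by Q10^((T−23)/10); steady states and conductances are
unchanged.  Defaults simulate at the 23 °C base.

## Source-constant repairs (and what was *not* changed)

The source description of this model contains transcription defects.
Three repairs were made, each forced by a dynamical impossibility and
resolved with the model's own published lineage; nothing else was
altered:

1. **Signs.**  The printed membrane equation (dV/dt = −I_app − …) and
   gating form ((x − x_∞)/τ) are anti-attracting and unstable; the
   standard attracting forms above are used.
2. **Units of g_Na, g_Kv3.**  Printed as 0.1125 and 0.223 mS/cm²
   ("retained" lineage values), three orders of magnitude too small to
   spike; read as S/cm² (the lineage fast-spiking values 112.5 and
   ~223–225 mS/cm²).
3. **τ_h.**  Printed as 7/(1+exp((V+60)/12)).  With that form the fast
   subsystem has *no Hopf bifurcation at any (q, I_app)* and the model
   cannot fire tonically at 450 pA — contradicting every reported
   behaviour.  The lineage form 0.5 + 14/(1+exp((V+60)/12)) restores
   the whole published structure (tonic firing at 450 pA, a
   subcritical Hopf in q, a discontinuous ~40 Hz f/I onset without
   Kv1) and is used.

E_L and the cell geometry are not stated in the source; E_L = −70 mV
is both the lineage value and the value at which the analytic DC input
resistance at rest equals the published 80.6 MΩ to three digits (the
model then rests at −70.2 mV).  The area follows from the published
capacitance.  These are calibrated values, not the original authors'.

### Known residual deviations

With the repaired kinetics the reconstruction is close but not
identical to the published model.  Verified non-numerical (stable
under 10× finer time steps and explicit-m integration):

* Hopf at 450 pA: q = 0.0684 here vs 0.05764 published (the location
  is hypersensitive to kinetic constants — ±2 mV in V_h moves it from
  0.27 to nonexistent — so this residual is within transcription
  uncertainty of the unpublished exact equations).
* Saddle-node of periodics: q = 0.437/0.276 at 450/330 pA vs ~0.3/~0.18
  published; our stable cycle survives to systematically higher q.
  Consequently at (g_Kv1 = 5 mS/cm², 330 pA) the q reached during
  firing equilibrates ~2% *below* the SNPO and the model fires
  tonically instead of bursting; the bursting regime exists but sits
  at higher g_Kv1 (e.g. 10 mS/cm², 285–390 pA, multi-second periods)
  or slightly lower current.
* Noise-calibration sigma: 169.6 pA vs 164.7 published (3%).
* Noisy interruption statistics inherit the cycle-robustness offset:
  3 of 10 calibrated-noise trials are never captured into quiescence
  (capture is a race between collapse onto the fixed point and q
  decaying back below the SNPO), giving mean ≈ 283 ms / SD ≈ 202 ms vs
  555.2 ± 39.5 ms published.

These were deliberately left as measured: the only constants with
demonstrable defects were repaired from the lineage, and adjusting
further constants toward the published summary numbers would be curve
fitting against equations we cannot see.

## Numerical methods

* **Integration.**  Fixed-step, numba-compiled.  Deterministic runs:
  classic RK4 at dt = 0.025 ms with the 1 µs Na-activation gate slaved
  to m_∞(V) (instantaneous); the approximation changes the steady
  450 pA rate by <1% against explicit integration (exponential
  Euler/Rush–Larsen for gates at dt = 0.005 ms), and halving dt
  changes it by <1%.  Stochastic runs: forward Euler at dt = 0.025 ms
  with one independent zero-mean Gaussian current sample of the stated
  sigma per step, so a (protocol, dt, seed) triple is bit-reproducible.
  The noise-update interval is a modelling choice (the source states
  only the sigma); it is recorded in every result's metadata.
* **Spike detection.**  Upward crossings of 0 mV with a 1 ms lockout;
  the reported time is the local voltage maximum after the crossing.
* **Equilibria and continuation.**  At a frozen-q equilibrium every
  fast gate sits on its steady-state curve, so equilibria reduce to a
  scalar current balance in V; branches are traced by secant-predictor
  / Newton-corrector pseudo-arclength continuation (step-halving on
  corrector failure) and cross-checked against the closed-form
  parametrisation q_eq(V), which is exact because I_Kv1 is linear
  in q.  Stability comes from the (V, h, n, p) Jacobian (finite
  differences) matching the integrator's instantaneous-m reduction.
* **Hopf detection.**  Sign change of the leading complex-pair real
  part along the branch, bisected to |Re λ| < 1e−8.  Criticality is
  labelled from the emanating cycle (subcritical if a small
  perturbation on the unstable side grows to spiking amplitude), not
  from the first Lyapunov coefficient.
* **Limit cycles.**  Stable cycles by long integration from a spiking
  initial condition (transient discarded; V max/min and period from
  the spike returns).  The unstable cycle's amplitude by bisection of
  the basin boundary along a V-ray from the stable equilibrium
  (bracket < 0.05 mV); only the amplitude is needed for the diagrams,
  so no periodic-orbit collocation is performed.  The SNPO is the
  largest q retaining a stable cycle, bisected to Δq < 1e−3.
* **Degenerate inputs.**  τ_q is floored at 0.1 ms below −105 mV to
  keep the vector field well-posed; integration aborts with the
  offending time if the state leaves (−200, 200) mV or turns
  non-finite; equilibrium and threshold searches raise explicit
  errors when brackets fail.

## Measurement conventions

* **Passive properties.**  R_in is the steady-state ΔV/ΔI of a
  symmetric pair of ±≈2 mV current steps at rest (the pair cancels the
  I–V curvature); τ is a three-parameter monoexponential fit to the
  full 400 ms charging curve of a ≈10 mV hyperpolarizing step;
  C = τ/R.  This emulates the published voltage-step protocol, which a
  current-clamp pipeline cannot perform literally.
* **Interruption duration.**  From mock-IPSP offset to the next spike;
  0 if a spike lands within one pre-IPSP ISI of the offset; flagged
  permanent-within-horizon if firing never resumes.  The source never
  defines the measurement; this definition is used consistently.
* **Noise sigma.**  The constant current that shifts the frozen-q
  Hopf-point equilibrium by −5 mV, obtained in closed form from the
  steady-state I–V relation and verified by a root solve to 0.01 mV.
* **Rescue threshold.**  Bisection (bracket < 0.05 nS, upper bound
  100 nS) on the peak of a biexponential conductance (0.5 ms rise,
  1 ms decay) for ≥1 spike within 100 ms of delivery; "shortly after
  the IPSP" defaults to a 50 ms delivery delay.
* **Minimum sustained frequency.**  ISIs > 1.5× the mean are treated
  as stutter gaps and removed in a single pass against the initial
  mean (the published wording is ambiguous about iteration), then
  f = 1000/mean ISI.
* **Regime labels.**  3 s step from rest.  Quiescent: no spikes.
  Elliptical bursting: ≥2 silent gaps > 5× the median ISI separating
  spike epochs, counting the trailing silence so slow burst cycles
  only partially covered by the record are recognised.  Transient:
  spikes but none in the final 1 s and no resumption after a gap.
  Tonic: otherwise; a single internal pause with firing through the
  end of the record is ambiguous between delayed tonic and a
  longer-than-record burst period and is tie-broken to tonic.

## Synthetic data

Two seeded generators make every analyzer testable without the
biophysical model.  Stimulus sampling renders the protocol segments
(steps, ramps, per-step Gaussian noise, biexponential conductances
with exactly-normalized peak) on the integration grid.  Surrogate
voltage traces place stereotyped triangular spikes (2 ms base — shape
is irrelevant to threshold-crossing detection) in regular trains with
optional stutter gaps and Gaussian baseline noise, returning the
ground-truth spike times and gap intervals; the noiseless analyzers
recover these exactly.  What the surrogates deliberately do not
emulate: real spike waveforms, bursty ISI jitter, channel noise — so
passing those tests validates the measurement rules, not the
biophysics.

## Temperature

Rerun at 32 °C (Q10 = 2, base 23 °C) the model still fires tonically
at 450 pA and the mock IPSP still silences it far beyond the pre-IPSP
ISI.  In this reconstruction the faster gate kinetics stabilise the
frozen-q equilibrium at every q (the Hopf disappears), so the
interruption becomes permanent within any simulated horizon rather
than ending by a Hopf crossing; the published account instead reports
a Hopf shifted to more hyperpolarized potentials with eventual
resumption.

## Problem sizes

Defaults were chosen as the smallest that resolve the slow q dynamics:
3 s steps for regime classification (burst periods up to multi-second
are handled by counting the trailing silence), 3 s pre-IPSP holds
(q reaches its firing steady state in ≈2 s), 4 s post-IPSP horizons
(noiseless interruption ≈1.5 s), 10 noisy trials per statistic, and
the 11 × 34 published grid for the phase diagram.

## Scope limits

Single compartment only; no channel noise; no synaptic network.  The
mEC comparison model is an interface (`pvin.via_ref`) whose equations
must be transcribed from its original publication; no part of the CA1
analysis depends on it.
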