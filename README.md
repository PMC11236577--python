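# pvin — persistent interruption of firing in PV interneurons

Fast-spiking, parvalbumin-expressing interneurons (PV-INs) can be
silenced by a brief inhibitory input for hundreds of milliseconds
*after* the inhibition has dissipated — a "persistent interruption" of
firing that disinhibits downstream pyramidal cells and is a candidate
substrate for persistent activity.  This package implements a
single-compartment conductance-based model of a hippocampal CA1 PV-IN
whose slowly inactivating Kv1 current produces that behaviour, plus the
full analysis pipeline around it: deterministic and stochastic
simulation under composable stimulus protocols, fast/slow bifurcation
analysis, firing-regime classification, and the derived
electrophysiology-style measurements.

## The model

Membrane equation (densities, µA/cm²):

    C_M dV/dt = I_app − g_L (V−E_L) − g_Kv3 n² (V−E_K)
                      − g_Kv1 p q (V−E_K) − g_Na m³ h (V−E_Na)

with first-order gating dx/dt = (x_∞(V) − x)/τ_x(V) for
x ∈ {m, h, n, p, q}.  The Na⁺ and Kv3 kinetics are the standard
fast-spiking (Erisir/Golomb lineage) forms; the distinguishing current
is Kv1, whose activation p is fast (τ_p = 0.448 ms) but whose
inactivation gate q is *slow and voltage dependent*,
τ_q = k(V+105) ms with k = 7.5, i.e. hundreds of milliseconds at
depolarized potentials but fast during the spike
afterhyperpolarization.  q is therefore the slow variable of a
fast/slow system, and freezing it as a bifurcation parameter exposes
the mechanism:

* the fast subsystem has a **subcritical Hopf bifurcation** in q — a
  depolarized quiescent fixed point coexists with the tonic-firing
  limit cycle (type 2 excitability, discontinuous f/I);
* a mock IPSP (step decrement + linear ramp of the holding current)
  drops the trajectory inside the unstable cycle onto the stable fixed
  point; firing stays off while q slowly decays, and resumes only
  after q crosses the Hopf and the subthreshold oscillation regrows —
  silence that long outlasts the stimulus;
* at lower holding currents the same structure, crossed periodically
  from both sides (Hopf on one side, a **saddle-node of periodics** on
  the other), yields elliptical bursting ("stuttering").

Parameter sets live in `src/pvin/configs/` (`ca1_chamberland_modified`
is the default; the leak reversal E_L = −70 mV and the membrane area
5.09×10⁻⁵ cm² are calibration choices documented in
`docs/methods.md`, which also records two places where the printed
source constants were defective and the lineage forms were used).

## Worked example

```python
from pvin import analysis as an, bifurcation as bf
from pvin.params import load_params

p = load_params("ca1_chamberland_modified")

props = an.measure_passive(p)
# R_in = 80.7 MOhm, tau = 4.04 ms, C = 50.0 pF

branch = bf.continue_equilibria(p, 450.0, (0.4, 0.0))
hopf = bf.detect_hopf(branch, p, I_app_pA=450.0, classify=True)[0]
# Hopf at q = 0.06843, subcritical

res, out = an.run_interruption(p)   # 450 pA hold, 100 pA/200 ms IPSP
# out.duration_ms = 1523 ms of silence beyond the IPSP
# (pre-IPSP ISI is 13.4 ms: the interruption outlasts it 100-fold)

sigma = an.calibrate_noise_sigma(p, hopf)   # 169.6 pA (5 mV rule)
```

The passive numbers mean the model matches the recorded cells' input
resistance and membrane time constant; the Hopf value is the Kv1
availability below which the quiescent state loses stability; the
interruption duration is the silence measured from IPSP offset to the
next spike.

The numbered drivers under `analysis/` chain these stages and write
tables to `results/` (01 passive calibration, 02 f/I curves, 03 the
interruption with its fast/slow overlay, 04 bifurcation diagrams,
05 elliptical bursting, 06 the (g_Kv1, I_app) phase diagram, 07 noise
robustness, 08 synaptic rescue thresholds).  The same stages are
exposed as a CLI:

```sh
pvin passive --out results/passive.csv
pvin bifurcate --i-app 450 --out results/branch.csv
pvin interruption --seed 1 --out results/trials.csv
```

The mEC comparison model used in the applied-current bistability
analysis ships as an interface only (`pvin.via_ref`); its equations
must be supplied from the original publication, and every CA1 analysis
runs without it.

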