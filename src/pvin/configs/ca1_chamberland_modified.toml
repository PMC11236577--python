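# CA1 fast-spiking PV-interneuron model (modified variant) — the
# default parameter set of this package.
#
# Conductances in mS/cm^2, potentials in mV, times in ms, capacitance
# in µF/cm^2, area in cm^2.  g_Na and g_Kv3 are the Erisir/Golomb-
# lineage fast-spiking values.  area is fixed so that the whole-cell
# capacitance is 50.9 pF; E_L is calibrated so the resting input
# resistance is 80.6 MΩ (see docs/methods.md for both calibrations).

[model]
name = "ca1_chamberland_modified"
C_M = 1.0
area = 5.09e-5
g_L = 0.25
g_Kv3 = 223.0
g_Kv1 = 5.0
g_Na = 112.5
E_L = -70.0
E_K = -90.0
E_Na = 50.0
V_h = -22.0
k = 7.5
tau_m = 0.001
tau_p = 0.448
tau_h_floor = 0.5
tau_h_amp = 14.0
tau_q_floor = 0.1
tau_q_mode = "linear"
temperature = 23.0
T_base = 23.0
Q10 = 2.0
length_um = 126.0
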