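# Golomb-like variant: identical fast kinetics but a voltage-
# INDEPENDENT Kv1 inactivation time constant of 150 ms, the defining
# difference of the neocortical-lineage description (its Kv1 window
# current at rest produces delayed firing rather than transient
# firing).  Only the tau_q description is changed here; the remaining
# constants are shared with the CA1 variant, hence "like".

[model]
name = "golomb_like"
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
tau_q_mode = "constant"
tau_q_const = 150.0
temperature = 23.0
T_base = 23.0
Q10 = 2.0
length_um = 126.0
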