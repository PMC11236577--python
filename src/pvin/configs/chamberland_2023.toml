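# Pre-modification CA1 PV-IN variant: the parameter set before the
# changes listed for the CA1 model (smaller leak, stronger Kv1, Na
# half-activation at -24 mV, steeper tau_q slope k = 10, 10 µm cell).
# The membrane area is scaled from the default variant by the length
# ratio (10/126); the source states the length but not the diameter.

[model]
name = "chamberland_2023"
C_M = 1.0
area = 4.04e-6
g_L = 0.1
g_Kv3 = 223.0
g_Kv1 = 10.0
g_Na = 112.5
E_L = -70.0
E_K = -90.0
E_Na = 50.0
V_h = -24.0
k = 10.0
tau_m = 0.001
tau_p = 0.448
tau_h_floor = 0.5
tau_h_amp = 14.0
tau_q_floor = 0.1
tau_q_mode = "linear"
temperature = 23.0
T_base = 23.0
Q10 = 2.0
length_um = 10.0
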