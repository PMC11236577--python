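# TEMPLATE for the mEC PV-IN comparison model (optional extra).
#
# The full equation set of this model is not distributed with the
# package; it must be transcribed from the source publication.  Fill
# in every section and register the right-hand side with
# pvin.via_ref.register_ec_model() — until then any mEC analysis
# raises a "reference equations required" error and every CA1
# analysis runs without it.

[ec_model]
provenance = ""            # REQUIRED: cite the source publication
C_M = 1.0                  # µF/cm^2
# area_cm2 = 0.0           # REQUIRED for pA <-> µA/cm^2 conversion

[ec_model.conductances_mS_cm2]
# g_Na = 0.0
# g_Kdr = 0.0
# g_L = 0.0

[ec_model.reversals_mV]
# E_Na = 0.0
# E_K = 0.0
# E_L = 0.0

[ec_model.kinetic_constants]
# gating midpoints, slopes and time constants from the publication
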