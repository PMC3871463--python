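# EA+-like preset: strongest outward rectification; slow activation component whose
# bell-shaped tau(V) carries 0.88 equivalent charges (za+zb).
[meta]
name = ea_like
schema = 1
description = symmetrical ethylammonium; steep Po(V), tau_act bell with z_eq = 0.88

[po]
A = 1.0
vmid1_mV = 40.051
k1_mV = 28.887651276509405
vmid2_mV = 40.051
k2_mV = 28.887651276509405

[rates]
a0_per_ms = 0.5
b0_per_ms = 2.0
za_e0 = 0.44
zb_e0 = 0.44

[permeation]
g_plus_pS = 25.0
g_minus_pS = 40.0
v_s_mV = 80.0

[channel]
n_channels = 10000
sigma_o_over_i = 0.1

[sensor]
z_e0 = 2.0
n_channels = 30000
a0_per_ms = 0.5
b0_per_ms = 0.5
za_e0 = 1.0
zb_e0 = 1.0
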