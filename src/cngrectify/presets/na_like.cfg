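# Na+-like preset: near-linear I-V, weak voltage gating (schema v1)
[meta]
name = na_like
schema = 1
description = symmetrical Na+; ohmic 30 pS pore, mild open-probability voltage dependence

[po]
A = 1.0
vmid1_mV = -350.0
k1_mV = 70.0
vmid2_mV = -350.0
k2_mV = 70.0

[rates]
a0_per_ms = 1.2
b0_per_ms = 0.4
za_e0 = 0.3
zb_e0 = 0.3

[permeation]
g_plus_pS = 30.0
g_minus_pS = 30.0
v_s_mV = 60.0

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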