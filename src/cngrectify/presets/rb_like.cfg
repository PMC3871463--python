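# Rb+-like preset: inward open-pore rectification (~3x chord ratio), modest gating
[meta]
name = rb_like
schema = 1
description = symmetrical Rb+; gamma ratio ~3 from +200 to -200 mV, Po drops ~25 percent

[po]
A = 1.0
vmid1_mV = -280.0
k1_mV = 70.0
vmid2_mV = -280.0
k2_mV = 70.0

[rates]
a0_per_ms = 0.5
b0_per_ms = 0.55
za_e0 = 0.22
zb_e0 = 0.22

[permeation]
g_plus_pS = 28.0
g_minus_pS = 95.0
v_s_mV = 70.0

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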