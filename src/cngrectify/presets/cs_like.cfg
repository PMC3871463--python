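# Cs+-like preset: strong inward open-pore rectification (~4x), Po drops ~55 percent
[meta]
name = cs_like
schema = 1
description = symmetrical Cs+; inwardly rectifying macroscopic I-V driven by gamma_sc

[po]
A = 1.0
vmid1_mV = -180.0
k1_mV = 90.0
vmid2_mV = -180.0
k2_mV = 90.0

[rates]
a0_per_ms = 0.35
b0_per_ms = 0.45
za_e0 = 0.22
zb_e0 = 0.22

[permeation]
g_plus_pS = 25.0
g_minus_pS = 115.0
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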