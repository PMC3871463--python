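# MA+-like preset: moderate outward rectification driven by Po
[meta]
name = ma_like
schema = 1
description = symmetrical methylammonium; outward I-V, |I+200/I-200| ~ 3

[po]
A = 0.85
vmid1_mV = -160.0
k1_mV = 40.0
vmid2_mV = 130.0
k2_mV = 25.0

[rates]
a0_per_ms = 0.4
b0_per_ms = 0.7
za_e0 = 0.3
zb_e0 = 0.12

[permeation]
g_plus_pS = 18.0
g_minus_pS = 30.0
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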