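# spHCN-like preset: hyperpolarization-activated control channel whose gating
# currents (40-50 pA from giant patches) are large enough for reliable Q(V)
# integration; the sensor moves ~6 e0 across ~7e4 channels (Q_max ~ 67 fC).
[meta]
name = sphcn_like
schema = 1
description = sea-urchin spHCN control; resolvable gating currents for Q(V) work

[po]
A = 1.0
vmid1_mV = -75.0
k1_mV = -15.0
vmid2_mV = -75.0
k2_mV = -15.0

[rates]
a0_per_ms = 0.4
b0_per_ms = 0.4
za_e0 = 0.5
zb_e0 = 0.5

[permeation]
g_plus_pS = 30.0
g_minus_pS = 30.0
v_s_mV = 60.0

[channel]
n_channels = 10000
sigma_o_over_i = 0.1

[sensor]
z_e0 = 6.0
n_channels = 70000
a0_per_ms = 0.33
b0_per_ms = 0.33
za_e0 = 0.5
zb_e0 = 0.5
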