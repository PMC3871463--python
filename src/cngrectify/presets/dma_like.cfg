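# DMA+-like preset: two gating transitions with a tail-current plateau around 0 mV;
# Po nearly constant on (-200, -100) mV while the open-pore conductance still grows
# with hyperpolarization, so sigma^2/I rises more than linearly with |V| there.
[meta]
name = dma_like
schema = 1
description = symmetrical dimethylammonium; two-component voltage gating, outward I-V

[po]
A = 0.6
vmid1_mV = -50.0
k1_mV = 14.866159721244607
vmid2_mV = 130.73
k2_mV = 23.758068339559139

[rates]
a0_per_ms = 0.4
b0_per_ms = 0.7
za_e0 = 0.3
zb_e0 = 0.12

[permeation]
g_plus_pS = 15.0
g_minus_pS = 60.0
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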