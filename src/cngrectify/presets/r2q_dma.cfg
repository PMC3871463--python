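# R2Q_WT tandem construct in symmetrical DMA+: the early transition is shallower
# (z1=1.04, Vmid1=-53.01 mV) while the late one is unchanged within error
# (z2=0.98, Vmid2=+120.37 mV).
[meta]
name = r2q_dma
schema = 1
description = R2Q_WT CNGA1 tandem in symmetrical DMA+; published two-Boltzmann fit

[po]
A = 0.6
vmid1_mV = -53.01
k1_mV = 24.443397233969498
vmid2_mV = 120.37
k2_mV = 25.93993176870232
  
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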