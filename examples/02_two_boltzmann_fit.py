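"""Fit a two-component Boltzmann to normalized DMA⁺ tail currents.

Tail curves in dimethylammonium show two separate voltage-dependent
transitions; fitting A·B1(V) + (1−A)·B2(V) to the min-subtracted tail curve
recovers both half-activation voltages and, via z = RT/(kF), the equivalent
gating charge of each transition.
"""

import numpy as np

import cngrectify as cg
from cngrectify.tail_analysis import CurveTable

model = cg.load_preset("wt_dma")  # activation parameters of the WT channel in DMA+
protocol = cg.build_tail_protocol(hold=0, pre_from=-180, pre_to=200, dV=20,
                                  pre_dur=100.0, tail_V=-200, tail_dur=5.0)

# six patches pooled, as is standard for activation curves
curves = []
for patch in range(6):
    rec = cg.simulate_macroscopic(model, protocol, cg.NoiseSpec(seal_rms=1.0),
                                  seed=3 + patch)
    tails = cg.isochronal_tails(rec, mode="extrapolate")
    curves.append(cg.normalize_tails(tails, mode="minsub").y)
curves = np.asarray(curves)  # (I_t − I_min)/(I_+200 − I_min) per patch
V = cg.normalize_tails(cg.isochronal_tails(rec, mode="extrapolate"), mode="minsub").V
pooled = CurveTable(V, curves.mean(axis=0))
fit = cg.fit_two_boltzmann(pooled)

print(fit)
truth = model.po_law
print(
    f"\ngenerator truth: A = {truth.A}, V_mid1 = {truth.c1.V_mid} mV "
    f"(z1 = {truth.c1.z():.2f}), V_mid2 = {truth.c2.V_mid} mV (z2 = {truth.c2.z():.2f})"
)
print(
    "\nThe steep low-voltage component (z1 ≈ 1.7) and the shallow"
    "\ndepolarized component (z2 ≈ 1.1) are recovered from the simulated"
    "\npatch; z_i converts each slope factor into elementary charges moved."
)
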