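"""Dissect rectification of a Cs⁺-like patch into gating and pore components.

Simulates a 10⁴-channel excised patch under the standard tail protocol
(prepulses −200…+200 mV, tail at −200 mV), then recovers the open-probability
ratio from isochronal tails, the conductance ratio from the steady currents,
and their quotient — the open-pore rectification γ_sc(V)/γ_sc(+200).
"""

import numpy as np

import cngrectify as cg

model = cg.load_preset("cs_like")
protocol = cg.build_tail_protocol(hold=0, pre_from=-200, pre_to=200, dV=20,
                                  pre_dur=100.0, tail_V=-200, tail_dur=5.0)
rec = cg.simulate_macroscopic(model, protocol, cg.NoiseSpec(seal_rms=1.0), seed=7)

tails = cg.isochronal_tails(rec, mode="extrapolate")
po_ratio = cg.normalize_tails(tails, mode="plain")      # P_o(V)/P_o(+200)
g_ratio = cg.steady_conductance(rec, window=20.0)       # G(V)/G(+200)
common = np.intersect1d(g_ratio.V, po_ratio.V)
gamma = cg.gamma_ratio(g_ratio.restrict(common), po_ratio.restrict(common))

print(f"{'V (mV)':>8} {'G ratio':>9} {'Po ratio':>9} {'gamma ratio':>12} {'true gamma':>11}")
for V, g, p, gm in zip(gamma.V, g_ratio.restrict(common).y,
                       po_ratio.restrict(common).y, gamma.y):
    print(f"{V:8.0f} {g:9.3f} {p:9.3f} {gm:12.3f} "
          f"{model.gamma(V) / model.gamma(200.0):11.3f}")

print(
    "\nG > 1 at negative voltages (inward rectification) while the Po ratio"
    "\nfalls below 1 there: the open pore conducts better at hyperpolarized"
    "\nvoltages even though channels are less likely to be open — the gamma"
    "\nratio isolates that open-pore component and matches the generator law."
)
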