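"""Stationary noise analysis: σ²/I against the i_sc(1−P_o) prediction.

For a homogeneous two-state population the variance-to-mean ratio of the
steady current equals the single-channel current times the closed
probability.  The measured ratio (background-subtracted) is compared with
the model prediction, and inverted at +60 mV for the absolute open
probability.
"""

import numpy as np

import cngrectify as cg

model = cg.load_preset("cs_like")
protocol = cg.build_tail_protocol(hold=0, pre_from=-200, pre_to=200, dV=40,
                                  pre_dur=300.0, tail_V=-200, tail_dur=2.0)

# pool four repeats: the variance of a slowly fluctuating current needs a
# few seconds of stationary data per voltage to stabilize
var_c, var_s, i_mean = [], [], []
for rep in range(4):
    rec = cg.simulate_macroscopic(model, protocol, cg.NoiseSpec(seal_rms=1.0),
                                  seed=11 + 2 * rep)
    seal = cg.simulate_background(protocol, cg.NoiseSpec(seal_rms=1.0),
                                  seed=12 + 2 * rep)
    table = cg.variance_to_mean(rec, seal, window=250.0)
    var_c.append(table.var_cgmp), var_s.append(table.var_seal), i_mean.append(table.I_mean)
ratio = np.where(
    np.abs(np.mean(i_mean, 0)) > 1.0,
    (np.mean(var_c, 0) - np.mean(var_s, 0)) / np.mean(i_mean, 0), np.nan,
)
pred = cg.predicted_ratio(model, table.V)

print(f"{'V (mV)':>8} {'sigma²/I (pA)':>14} {'i_sc(1-Po) (pA)':>16}")
for V, r, p in zip(table.V, ratio, pred.y):
    shown = f"{r:14.3f}" if np.isfinite(r) else f"{'masked':>14}"
    print(f"{V:8.0f} {shown} {p:16.3f}")

V0 = 40.0
i = np.flatnonzero(table.V == V0)[0]
po, flagged = cg.absolute_po_from_noise(ratio[i], model.isc(V0))
print(f"\nabsolute P_o at +40 mV from noise: {po:.3f} "
      f"(generator truth {model.po(V0):.3f})")

print(
    "\nThe measured ratio tracks i_sc(1−P_o) across the grid; the large"
    "\nvalues at negative voltages reflect the big inward single-channel"
    "\ncurrent, not extra gating. Inverting the ratio anchors absolute P_o."
)
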