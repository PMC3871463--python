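"""Count channels two ways: macroscopic current and amplitude histograms.

A giant patch's channel count follows from N = I/(γ·V·P_o) (with the
blocker-corrected variant N = I/(γ·V·P_o·α) when an impermeant cation
carries the pipette solution).  A near-single-channel patch is counted
instead from the Gaussian components of its all-point amplitude histogram.
"""

import cngrectify as cg

# --- macroscopic counting: the printed worked examples -------------------
direct = cg.count_channels(I=1000.0, V=60.0, gamma=30.0, Po=0.8)
giant = cg.count_channels(I=1e4, V=10.0, gamma=30.0, Po=0.8)
blocked = cg.count_channels_blocked(I=2e4, V=60.0, gamma=30.0, Po=0.8, alpha=0.48)
print(direct)
print(giant)
print(blocked)

# --- histogram counting on a simulated two-channel patch -----------------
law = cg.TwoBoltzmann(1.0, cg.BoltzmannComponent(100.0, 25.0),
                      cg.BoltzmannComponent(100.0, 25.0))
model = cg.ChannelModel(po_law=law, rate_law=cg.RateLaw(0.05, 0.1, 0.05, 0.1),
                        perm=cg.PermeationLaw(30.0, 30.0, 60.0), N=2,
                        name="two_channel_patch")
protocol = cg.build_tail_protocol(100, 100, 100, 20, 1500.0, 100, 10.0)
rec, _ = cg.simulate_single_channel(model, protocol, cg.NoiseSpec(1.0), seed=5)
fit = cg.count_channels_from_histogram(rec, seed=0)
print()
print(fit)

print(
    "\nThe macroscopic equation turns a 1 nA current into ~700 channels and"
    "\na 20 nA TEA-blocked current into ~2.9×10⁴; the histogram of the small"
    "\npatch needs three Gaussian levels (closed, one open, two open), i.e."
    "\ntwo channels."
)
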