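# Methods

This note records the models, numerical choices and known limitations of
the package. Voltages are mV, times ms, currents pA, conductances pS and
charges fC throughout; RT/F at the default temperature of 295 K is
25.42 mV, and the elementary charge is taken as e₀ = 1.6×10⁻¹⁹ C.

## Channel model

A channel is described by four independent laws:

* **Equilibrium open probability** — a weighted sum of two Boltzmann
  sigmoids, P_o(V) = A·B₁(V) + (1−A)·B₂(V) with
  Bᵢ(V) = 1/(1+exp((V_midᵢ−V)/kᵢ)). Slope factors are stored in mV and
  convert to equivalent charges as zᵢ = RT/(kᵢF). The weight A is a free
  parameter (no published estimate exists); presets use A = 0.6.
* **Relaxation kinetics** — Eyring-form rates α(V) = a₀·exp(z_a FV/RT),
  β(V) = b₀·exp(−z_b FV/RT) giving τ(V) = 1/(α+β). Where a τ(V) law was
  fitted without separately resolved forward/backward rates, the charge is
  split evenly (z_a = z_b) — the minimal standard assumption.
* **Open-pore current** — i_sc(V) = γ(V)·V/1000 with a sigmoidal chord
  conductance γ(V) = g₊ + (g₋−g₊)/(1+exp(V/V_s)). This is a deliberately
  parametric stand-in for the empirical single-channel rectification of
  each ion; presets are calibrated to the qualitative conductance ratios
  (γ(−200)/γ(+200) ≈ 3 for Rb⁺-like, ≈ 4 for Cs⁺-like, outward for the
  organic cations), not fitted to raw traces. In symmetrical solutions
  i_sc(0) = 0 by construction.
* **Voltage sensor** — a two-state charge of z e₀ per channel with its own
  rate law; the ensemble gating current is I_g = z·e₀·N·dm/dt where m is
  the activated fraction.

The package does not model the kinetic scheme that would couple the two
Boltzmann components (none is established): simulations use effective rates
α_eff = P_o(V)/τ(V), β_eff = (1−P_o(V))/τ(V), so the *equilibrium* follows
the full two-component law while the *relaxation* follows the single fitted
τ(V). Multi-exponential relaxations are therefore reproduced only through
their dominant component.

## Synthetic patches

`simulate_macroscopic` propagates the open-channel count with the exact
two-state transition matrix per 0.02 ms sample (50 kHz): an open channel
stays open with probability p+(1−p)e^(−dt/τ), a closed one opens with
p(1−e^(−dt/τ)), p = P_o(V). This keeps the stationary moments exactly
binomial at any N — mean N·i_sc·P_o, variance N·i_sc²·P_o(1−P_o) — which
the noise analysis relies on. Seal noise is generated white at the sampling
rate, scaled by the filter's equivalent noise bandwidth and passed through
the 10 kHz 4-pole Bessel filter, so the quoted r.m.s. (1 pA by default)
refers to the stated bandwidth. The channel-borne component of the trace is
*not* refiltered: its fluctuations live far below the 10 kHz cutoff (gating
corner frequencies are 0.1–0.5 kHz), and leaving it unfiltered keeps the
binomial variance law exact; recordings carry `signal_filtered: False` in
their metadata so the analyses know that no filter delay applies to the
deterministic component. Random streams are split per sweep from the master
seed; identical seed and configuration give bit-identical sweeps.

`simulate_single_channel` (N = 1 or 2) is an exact event-driven (Gillespie)
simulation of the two-state chain; open samples can carry extra Gaussian
open-channel noise σ_o = (σ_o/i_sc)·i_sc, default ratio 0.1.

`simulate_gating_currents` emits the deterministic ensemble current with
each sample holding the exact bin-averaged q·Δm/dt, so the bin sum dt·ΣI
reproduces moved charge to machine precision; `n_average` emulates the
standard practice of averaging ~20 recordings per trace.

A linear RC membrane simulator exists solely to exercise the P/−4
subtraction; capacitive artifacts are otherwise off — analyses assume
leak-corrected input, and the isochronal blanking windows default to small
values accordingly.

## Analysis choices

* **Isochronal tails** offer three modes: `point` (default latency 0.5 ms
  after tail onset with a 0.1 ms averaging window), `peak`, and
  `extrapolate`, which fits I(t) = I_ss + A·e^(−t/τ) past the blanking
  window and back-extrapolates to the onset. Extrapolation is the preferred
  mode for the synthetic data because deactivation at −200 mV (τ ≈
  0.3–0.6 ms for the shipped presets) loses most of the P_o modulation
  within the first half millisecond. Back-extrapolation is refused when the
  fitted decay would amplify the window-start value by more than e² (the
  transient is then unresolved); the point estimate falls back to the first
  sample and the voltage is flagged.
* **Filter onset delay.** For data whose full signal passed the output
  filter, step onsets are shifted by the filter's low-frequency group delay
  (≈0.034 ms at 10 kHz) before isochronal indexing and extrapolation.
* **Normalization.** `minsub` computes (I_t − I_min)/(I_anchor − I_min),
  which is 0 at the minimum, 1 at the anchor (+200 mV by default, config-
  urable for protocols without it) and invariant to gain/offset of the raw
  amplitudes; orientation is fixed by requiring the anchor to carry the
  largest amplitude, so inward (negative) tail families normalize
  identically to outward ones. Because the two-Boltzmann model evaluates to
  slightly less than 1 at +200 mV, the forced unit anchor biases the
  recovered late component upward by roughly 1−P_o(+200) (a few percent);
  per-point SEM weighting should not be combined with points pinned by the
  normalization itself.
* **γ decomposition.** The G and P_o ratio curves must share a voltage
  grid; the V = 0 point is dropped (zero driving force), and quotient
  points with P_o ratio below 0.01 are masked rather than divided.
* **Two-Boltzmann fitting** uses bounded least squares with multiple
  starting points, per-point 1/SEM weights when pooled patches provide
  them, and reports asymptotic standard errors. Components are ordered by
  V_mid. Fits are declared degenerate when the weight hits a bound, the
  midpoints are closer than half a slope factor, or the normal-equation
  condition number exceeds 10¹⁰ — single-Boltzmann data triggers this
  rather than yielding a spurious second charge.
* **Activation kinetics** are fitted as a double exponential by variable
  projection (amplitudes solved linearly on a τ grid, then polished), with
  τ_f < τ_s enforced and identifiability flagged when τ_s/τ_f < 3. The
  bell fit recovers (a₀, b₀, z_eq) from τ(V) on the log scale, appropriate
  for multiplicative scatter.
* **Noise analysis** subtracts background on the variances (independent
  sources add in quadrature); `subtraction='rms'` reproduces the literal
  r.m.s. difference convention for comparison. The variance of a gating
  process with correlation time τ needs ~4τ/ε² of stationary data for a
  relative error ε, so grid-wide comparisons pool several sweeps per
  voltage (the tests use ≈5 s per voltage for ≤10% pointwise error).
* **Open-channel-noise bound.** With σ_e² = N·P_o·σ_o² on top of the
  gating variance, σ_tot/σ − 1 = √(1+(σ_o/i_sc)²/(1−P_o))−1: 22.5% at the
  worst plausible (0.5, 0.5), ~1% at the typical σ_o/i_sc = 0.1.
* **Histogram counting.** Traces are refiltered at 1 kHz, decimated to
  twice that bandwidth (so samples are approximately independent, as the
  BIC assumes) and fitted with Gaussian mixtures over 1–4 components.
  Model selection is BIC restricted to solutions whose components all
  carry ≥5% of the data, and components whose means sit within twice the
  wider s.d. are merged before counting levels — the likelihood otherwise
  splits the filter-smeared transition bridge or a skewed level into
  spurious components. Channel count = resolved levels − 1.
* **Charge integration** treats samples as bin averages and integrates by
  the exact bin sum dt·ΣI with optional baseline-segment subtraction; an
  endpoint trapezoid would lose the half-bins at the window edges, which
  matters for transients only a few samples wide.
* **Detectability map.** S/N = (z·e₀·N/τ)/r.m.s. by default (analytic
  exponential peak, bias-free); a simulated variant reads the noisy peak
  off simulated off-gating sweeps. Classes: S/N < 4 low, 4–6 mid, > 6
  high; defaults N = 3×10⁴ channels, 1 pA r.m.s.

## Presets and study conditions

Presets ship as versioned key-value config files. `wt_dma` and `r2q_dma`
carry the published two-Boltzmann activation parameters for the WT channel
and the R2Q_WT tandem construct in symmetrical DMA⁺ (z₁ = 1.71/1.04,
V_mid1 = −93.64/−53.01 mV; z₂ = 1.07/0.98, V_mid2 = +130.73/+120.37 mV).
The generic `dma_like` preset instead places the early transition at
−50 mV: the reported behaviour has P_o nearly constant between −200 and
−100 mV while σ²/I still grows more than linearly with |V| there, which the
published fit parameters cannot reproduce simultaneously; the two presets
keep both faces of the data available. `ea_like` carries the bell-shaped
activation-τ law with z_eq = 0.88; the same law makes deactivation at
−200 mV faster (≈0.016 ms) than a 10 kHz/50 kHz recording can resolve, so
tail-based P_o recovery is not expected for that preset and the round-trip
tests cover it through its conductance curve only. `sphcn_like` provides a
control sensor with large (40–50 pA) gating currents — z = 6, N = 7×10⁴,
Q_max ≈ 67 fC — for charge-integration work, matching the scale at which
Q(V) curves are measured reliably; at CNGA1 scale (z ≤ 2, N ≈ 3×10⁴,
Q_max = 9.6 fC) the statistical noise floor of a full-cycle charge integral
under 1 pA background exceeds the sub-percent regime even with 20-trace
averaging.

Default study conditions used across tests: N = 10⁴ channels for
macroscopic work (giant-patch scale), 1 pA seal r.m.s. at 10 kHz, 50 kHz
sampling, prepulse families −200…+200 mV in 20 mV steps with 100 ms
prepulses (the source protocols leave the prepulse duration unstated;
100 ms is config-exposed) and 5 ms tails at −200 mV. Test problem sizes
(number of pooled sweeps, recording lengths, seed counts) are chosen so
that the statistical error of each estimator sits a factor ≳3 below the
asserted tolerance.

## What the generator does and does not emulate

The synthetic patches reproduce the features the analyses are sensitive to:
binomial gating statistics, exponential relaxation with voltage-dependent
τ, open-pore rectification, band-limited background noise, and two-state
gating charge movement. They do not emulate proton block, flicker/
subconductance behaviour (beyond the σ_o term), rundown, series-resistance
artifacts, capacitive transients (beyond the optional linear RC used for
P/−4), or multi-exponential activation. Passing round trips therefore
demonstrate the correctness and calibration of the analysis chain under
the stated statistical model, not robustness to every pathology of real
recordings.

## File formats

Recordings are exchanged as a plain-text ATF dialect: line 1 `ATF<tab>1.0`,
line 2 `<n_header_records><tab><n_columns>`, optional `key=value` records
(filter cutoff, JSON metadata), one quoted column-title line, then
tab-separated rows of time (ms) and per-sweep currents (pA) at 10⁻⁶ pA
precision. Derived curves are CSV with columns `V_mV,value,sem,n`. Run
configs are strict-schema YAML; unknown keys are errors, and every run
writes a manifest (config hash, seed, versions) sufficient to reproduce it.
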