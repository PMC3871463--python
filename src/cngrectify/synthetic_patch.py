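"""Synthetic excised-patch recordings.

Stands in for real voltage-clamp data so every analysis stage can be tested
end-to-end: macroscopic currents from N independent two-state channels,
single-channel records (N = 1 or 2) from exact stochastic simulation, and
ensemble gating currents from a two-state voltage sensor.

Statistical structure the analyses rely on:

* at a steady voltage the open-channel count is Binomial(N, P_o(V)), so the
  mean current is N·i_sc·P_o and the gating variance N·i_sc²·P_o(1−P_o) —
  the variance-to-mean ratio is i_sc·(1−P_o);
* relaxation toward equilibrium follows the τ(V) = 1/(α+β) law;
* seal noise is white at the sampling rate and then passed through the
  10 kHz output filter, so its quoted r.m.s. (~1 pA) refers to that
  bandwidth, as on a real rig.

Kinetics use effective rates α_eff = P_o(V)/τ(V), β_eff = (1−P_o(V))/τ(V):
the equilibrium tracks the (possibly two-component) open-probability law
while the relaxation speed tracks the fitted τ law.  Random streams are
split per sweep from the master seed, so simulating sweeps in any order
gives the same traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .channel_model import CONSTANTS, ChannelModel, RateLaw, relaxation
from .errors import ParameterError
from .recordings_io import (
    SweepSet,
    VoltageProtocol,
    bessel_lowpass_sos,
    equivalent_noise_bandwidth_khz,
)
from scipy import signal as _signal

__all__ = [
    "NoiseSpec",
    "SensorSpec",
    "effective_rates",
    "simulate_macroscopic",
    "simulate_background",
    "simulate_single_channel",
    "sample_dwells",
    "simulate_gating_currents",
    "simulate_linear_leak",
    "build_p4_subsweeps",
]

DEFAULT_DT_MS = 0.02  # 50 kHz sampling
DEFAULT_FILTER_KHZ = 10.0


@dataclass(frozen=True)
class NoiseSpec:
    """Background (seal) noise: r.m.s. in pA at the stated filter bandwidth."""

    seal_rms: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        if self.seal_rms < 0:
            raise ParameterError("seal_rms must be non-negative")


@dataclass(frozen=True)
class SensorSpec:
    """Two-state voltage sensor: z elementary charges per channel, N channels."""

    z: float  # e0 per channel
    tau_law: RateLaw
    N: int

    def __post_init__(self):
        if self.z < 0 or self.N < 0:
            raise ParameterError("sensor charge z and channel count N must be non-negative")

    @property
    def q_max_fC(self) -> float:
        """Total movable charge z·e0·N in femtocoulombs."""
        return self.z * CONSTANTS.e0 * self.N * 1e15

    def m_inf(self, V) -> np.ndarray:
        """Equilibrium activated fraction of the sensor at V (mV)."""
        return relaxation(V, self.tau_law)[3]

    def tau(self, V):
        return relaxation(V, self.tau_law)[2]


def effective_rates(model: ChannelModel, V):
    """Opening/closing rates (ms⁻¹) with equilibrium P_o(V) and speed 1/τ(V)."""
    po = model.po(V)
    tau = model.tau(V)
    return po / tau, (1.0 - po) / tau


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _resolve_seed(seed, noise: NoiseSpec):
    if seed is None:
        seed = noise.seed
    if seed is None:
        raise ParameterError("a seed must be given (argument or NoiseSpec.seed)")
    return int(seed)


def _white_sigma(seal_rms: float, fs_khz: float, filter_khz: float | None) -> float:
    """Pre-filter white-noise sigma so the filtered trace has the quoted rms."""
    if seal_rms == 0:
        return 0.0
    if filter_khz is None:
        return seal_rms
    enb = equivalent_noise_bandwidth_khz(filter_khz, fs_khz)
    return seal_rms / np.sqrt(enb / (fs_khz / 2.0))


def _filter_traces(traces: np.ndarray, fs_khz: float, filter_khz: float | None) -> np.ndarray:
    if filter_khz is None:
        return traces
    sos = bessel_lowpass_sos(filter_khz, fs_khz)
    return _signal.sosfilt(sos, traces, axis=-1)


def _epoch_plan(prot: VoltageProtocol, sweep: int, dt: float):
    """Per-epoch (level, n_samples) with rounding that preserves the total."""
    n_total = prot.n_samples(dt)
    levels = prot.levels(sweep)
    edges = np.round(np.cumsum([0.0] + [e.duration for e in prot.epochs]) / dt).astype(int)
    edges[-1] = n_total
    return [(levels[i], edges[i], edges[i + 1]) for i in range(len(levels))]


# ---------------------------------------------------------------------------
# macroscopic simulation
# ---------------------------------------------------------------------------

def simulate_macroscopic(
    model: ChannelModel,
    prot: VoltageProtocol,
    noise: NoiseSpec,
    seed: int | None = None,
    dt: float = DEFAULT_DT_MS,
    filter_khz: float | None = DEFAULT_FILTER_KHZ,
    store_states: bool = False,
) -> SweepSet:
    """Macroscopic current sweeps from N independent two-state channels.

    Per time step the open count follows the exact two-state propagator:
    an open channel stays open with probability p + (1−p)·e^(−dt/τ), a
    closed one opens with probability p·(1−e^(−dt/τ)), where p = P_o(V).
    The current is n_open·i_sc(V) plus filtered seal noise.  With
    ``store_states`` the hidden n_open paths are kept in
    ``meta['n_open']`` (pre-filter) for oracle checks.
    """
    if model.N < 1:
        out = simulate_background(prot, noise, seed, dt=dt, filter_khz=filter_khz)
        out.meta["model"] = model.name
        return out
    seed = _resolve_seed(seed, noise)
    children = np.random.SeedSequence(seed).spawn(prot.n_sweeps)
    n_samp = prot.n_samples(dt)
    fs = 1.0 / dt
    sigw = _white_sigma(noise.seal_rms, fs, filter_khz)
    traces = np.empty((prot.n_sweeps, n_samp))
    states = np.empty((prot.n_sweeps, n_samp), dtype=np.int64) if store_states else None

    for s in range(prot.n_sweeps):
        rng = np.random.default_rng(children[s])
        n = rng.binomial(model.N, float(np.clip(model.po(prot.holding), 0, 1)))
        path = np.empty(n_samp, dtype=np.int64)
        isc_path = np.empty(n_samp)
        for level, i0, i1 in _epoch_plan(prot, s, dt):
            p = float(np.clip(model.po(level), 0.0, 1.0))
            decay = np.exp(-dt / model.tau(level))
            p_oo = p + (1.0 - p) * decay
            p_co = p * (1.0 - decay)
            isc = model.isc(level)
            binom = rng.binomial
            N = model.N
            for i in range(i0, i1):
                n = binom(n, p_oo) + binom(N - n, p_co)
                path[i] = n
            isc_path[i0:i1] = isc
        noise_tr = rng.normal(0.0, sigw, n_samp) if sigw > 0 else 0.0
        traces[s] = path * isc_path
        if sigw > 0:
            traces[s] += _filter_traces(noise_tr, fs, filter_khz)
        if store_states:
            states[s] = path

    meta = {
        "kind": "macroscopic", "model": model.name, "seed": seed, "units": "pA",
        "signal_filtered": False,
    }
    if store_states:
        meta["n_open"] = states
        meta["isc_by_sweep"] = np.array(
            [[model.isc(lv) for lv, _, _ in _epoch_plan(prot, s, dt)] for s in range(prot.n_sweeps)],
            dtype=object,
        )
    return SweepSet(dt=dt, traces=traces, protocol=prot, filter_cutoff=filter_khz, meta=meta)


def simulate_background(
    prot: VoltageProtocol,
    noise: NoiseSpec,
    seed: int | None = None,
    dt: float = DEFAULT_DT_MS,
    filter_khz: float | None = DEFAULT_FILTER_KHZ,
) -> SweepSet:
    """Paired no-ligand sweeps: seal noise only, same protocol and filtering."""
    seed = _resolve_seed(seed, noise)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0].spawn(1)[0])
    n_samp = prot.n_samples(dt)
    fs = 1.0 / dt
    sigw = _white_sigma(noise.seal_rms, fs, filter_khz)
    traces = rng.normal(0.0, sigw, (prot.n_sweeps, n_samp)) if sigw > 0 else np.zeros(
        (prot.n_sweeps, n_samp)
    )
    traces = _filter_traces(traces, fs, filter_khz)
    return SweepSet(
        dt=dt, traces=traces, protocol=prot, filter_cutoff=filter_khz,
        meta={"kind": "seal", "seed": seed, "units": "pA"},
    )


# ---------------------------------------------------------------------------
# single-channel simulation
# ---------------------------------------------------------------------------

def _gillespie_epoch(rng, state: int, alpha: float, beta: float, t0: float, t1: float):
    """Exact two-state trajectory on [t0, t1); yields (switch_time, new_state)."""
    events = []
    t = t0
    while True:
        rate = beta if state else alpha
        if rate <= 0:
            break
        t = t + rng.exponential(1.0 / rate)
        if t >= t1:
            break
        state = 1 - state
        events.append((t, state))
    return events, state


def simulate_single_channel(
    model: ChannelModel,
    prot: VoltageProtocol,
    noise: NoiseSpec,
    seed: int | None = None,
    dt: float = DEFAULT_DT_MS,
    filter_khz: float | None = DEFAULT_FILTER_KHZ,
):
    """Single-channel sweeps (N = 1 or 2) by exact event-driven simulation.

    Returns ``(SweepSet, state_path)`` where ``state_path`` is the hidden
    (sweeps × samples) open-channel count before noise and filtering.  Open
    samples optionally carry extra Gaussian open-channel noise of s.d.
    σ_o = sigma_o_over_i·|i_sc(V)|.
    """
    if model.N not in (1, 2):
        raise ParameterError(f"single-channel simulation needs N in {{1, 2}}, got {model.N}")
    seed = _resolve_seed(seed, noise)
    children = np.random.SeedSequence(seed).spawn(prot.n_sweeps)
    n_samp = prot.n_samples(dt)
    fs = 1.0 / dt
    sigw = _white_sigma(noise.seal_rms, fs, filter_khz)
    traces = np.zeros((prot.n_sweeps, n_samp))
    state_path = np.zeros((prot.n_sweeps, n_samp), dtype=np.int8)
    centers = (np.arange(n_samp) + 0.5) * dt

    for s in range(prot.n_sweeps):
        rng = np.random.default_rng(children[s])
        for _ch in range(model.N):
            p_hold = float(np.clip(model.po(prot.holding), 0, 1))
            state = int(rng.random() < p_hold)
            occ = np.zeros(n_samp, dtype=np.int8)
            for level, i0, i1 in _epoch_plan(prot, s, dt):
                a, b = effective_rates(model, level)
                events, state_end = _gillespie_epoch(
                    rng, state, float(a), float(b), i0 * dt, i1 * dt
                )
                seg_t = centers[i0:i1]
                seg = np.full(i1 - i0, state, dtype=np.int8)
                cur = state
                last = i0 * dt
                for t_ev, st in events:
                    seg[(seg_t >= last) & (seg_t < t_ev)] = cur
                    cur = st
                    last = t_ev
                seg[seg_t >= last] = cur
                occ[i0:i1] = seg
                state = state_end
            state_path[s] += occ
        isc_per_sample = np.concatenate(
            [np.full(i1 - i0, model.isc(level)) for level, i0, i1 in _epoch_plan(prot, s, dt)]
        )
        sig = state_path[s] * isc_per_sample
        if model.sigma_o_over_i > 0:
            open_mask = state_path[s] > 0
            sig = sig + open_mask * rng.normal(
                0.0, 1.0, n_samp
            ) * model.sigma_o_over_i * np.abs(isc_per_sample) * np.sqrt(state_path[s])
        if sigw > 0:
            sig = sig + _filter_traces(rng.normal(0.0, sigw, n_samp), fs, filter_khz)
        traces[s] = sig

    rec = SweepSet(
        dt=dt, traces=traces, protocol=prot, filter_cutoff=filter_khz,
        meta={
            "kind": "single_channel", "model": model.name, "seed": seed, "units": "pA",
            "signal_filtered": False,
        },
    )
    return rec, state_path


def sample_dwells(
    model: ChannelModel, V: float, n_dwells: int, seed: int, state: str = "open"
) -> np.ndarray:
    """Draw dwell times (ms) of the open or closed state at a fixed voltage.

    Dwells are exponential with rate β_eff (open) or α_eff (closed); used by
    distributional tests against the simulator.
    """
    a, b = effective_rates(model, V)
    rate = float(b if state == "open" else a)
    if rate <= 0:
        raise ParameterError(f"{state} state is absorbing at {V} mV (rate 0)")
    rng = np.random.default_rng(seed)
    return rng.exponential(1.0 / rate, n_dwells)


# ---------------------------------------------------------------------------
# gating currents
# ---------------------------------------------------------------------------

def simulate_gating_currents(
    sensor: SensorSpec,
    prot: VoltageProtocol,
    noise: NoiseSpec,
    seed: int | None = None,
    dt: float = DEFAULT_DT_MS,
    filter_khz: float | None = DEFAULT_FILTER_KHZ,
    n_average: int = 1,
) -> SweepSet:
    """Deterministic ensemble gating current plus seal noise.

    The activated fraction m(t) relaxes exponentially within each epoch
    toward m_inf(V) with time constant τ(V); the gating current is
    I_g(t) = z·e0·N·dm/dt (1 fC/ms = 1 pA).  On- and off-charges are equal
    and opposite, so the integral over a full activate–deactivate cycle
    vanishes.  ``n_average`` emulates averaging that many recordings, as is
    standard practice for gating-current measurements.
    """
    if n_average < 1:
        raise ParameterError("n_average must be >= 1")
    seed = _resolve_seed(seed, noise)
    children = np.random.SeedSequence(seed).spawn(prot.n_sweeps)
    n_samp = prot.n_samples(dt)
    fs = 1.0 / dt
    sigw = _white_sigma(noise.seal_rms, fs, filter_khz)
    q = sensor.q_max_fC
    traces = np.empty((prot.n_sweeps, n_samp))
    centers = (np.arange(n_samp) + 0.5) * dt

    for s in range(prot.n_sweeps):
        m = float(sensor.m_inf(prot.holding))
        ig = np.empty(n_samp)
        for level, i0, i1 in _epoch_plan(prot, s, dt):
            m_inf = float(sensor.m_inf(level))
            tau = float(sensor.tau(level))
            # each sample carries the exact bin-averaged current
            # q·Δm/dt, so dt·Σ(samples) reproduces the moved charge exactly
            t_edges = (np.arange(i0, i1 + 1) - i0) * dt
            m_path = m_inf + (m - m_inf) * np.exp(-t_edges / tau)
            ig[i0:i1] = q * np.diff(m_path) / dt
            m = float(m_path[-1])
        if sigw > 0:
            rng = np.random.default_rng(children[s])
            nz = rng.normal(0.0, sigw, (n_average, n_samp)).mean(axis=0)
            ig = ig + _filter_traces(nz, fs, filter_khz)
        traces[s] = ig

    return SweepSet(
        dt=dt, traces=traces, protocol=prot, filter_cutoff=filter_khz,
        meta={
            "kind": "gating", "seed": seed, "units": "pA",
            "q_max_fC": q, "n_average": n_average, "signal_filtered": False,
        },
    )


# ---------------------------------------------------------------------------
# linear membrane (for exercising P/−4)
# ---------------------------------------------------------------------------

def simulate_linear_leak(
    prot: VoltageProtocol,
    R_leak_MOhm: float,
    C_m_pF: float,
    dt: float = DEFAULT_DT_MS,
    filter_khz: float | None = None,
    scale: float = 1.0,
    access_tau_ms: float = 0.05,
) -> SweepSet:
    """Noise-free linear (RC) membrane response to ``scale``× the command.

    Ohmic leak V/R plus a capacitive transient C·dV/dt smoothed over the
    access time constant.  Being strictly linear in the command, this is
    exactly what the P/−4 procedure must cancel.
    """
    if R_leak_MOhm <= 0 or C_m_pF < 0:
        raise ParameterError("leak resistance must be positive, capacitance non-negative")
    n_samp = prot.n_samples(dt)
    centers = (np.arange(n_samp) + 0.5) * dt
    traces = np.empty((prot.n_sweeps, n_samp))
    for s in range(prot.n_sweeps):
        v = prot.command(s, centers) * scale  # mV
        i_ohm = v / R_leak_MOhm * 1000.0  # mV/MΩ = nA → pA
        # capacitive spike: jump ΔV charges C through the access resistance
        i_cap = np.zeros(n_samp)
        v_prev = prot.holding * scale
        start = 0.0
        for lvl, e in zip(prot.levels(s), prot.epochs):
            lvl = lvl * scale
            dV = lvl - v_prev
            if dV != 0 and C_m_pF > 0:
                t_rel = centers - start
                mask = t_rel >= 0
                i_cap[mask] += (
                    C_m_pF * dV / access_tau_ms * np.exp(-t_rel[mask] / access_tau_ms)
                )
            v_prev = lvl
            start += e.duration
        traces[s] = i_ohm + i_cap
    traces = _filter_traces(traces, 1.0 / dt, filter_khz)
    return SweepSet(
        dt=dt, traces=traces, protocol=prot, filter_cutoff=filter_khz,
        meta={"kind": "linear_leak", "units": "pA"},
    )


def build_p4_subsweeps(prot: VoltageProtocol) -> VoltageProtocol:
    """The −P/4 companion protocol: each sweep level appears four times at −1/4 amplitude."""
    quarter = [lv / -4.0 for lv in prot.sweep_levels for _ in range(4)]
    epochs = tuple(
        e if e.level is None else type(e)(e.level / -4.0, e.duration) for e in prot.epochs
    )
    return VoltageProtocol(
        holding=prot.holding / -4.0,
        epochs=epochs,
        sweep_levels=tuple(quarter),
        inter_sweep_ms=prot.inter_sweep_ms,
    )
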