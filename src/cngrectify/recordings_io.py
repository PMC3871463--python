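"""Voltage protocols, sweep containers, filtering, leak subtraction and file I/O.

The recording container mirrors what a patch amplifier delivers: a matrix of
current sweeps (pA) on a fixed sampling grid, tied to the voltage-command
protocol that elicited them.  Time origin is t = 0 at sweep start and epoch
boundaries are half-open [start, end).

Files use a plain-text Axon-Text-File (ATF) dialect: tab separated, one time
column (ms) plus one column per sweep (pA), a two-field version/size header
and optional ``key=value`` header records carrying the filter cutoff and
free-form metadata.  Derived curves travel as CSV tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .errors import AlignmentError, AtfParseError, ParameterError, ProtocolError

__all__ = [
    "Epoch",
    "VoltageProtocol",
    "SweepSet",
    "build_tail_protocol",
    "build_instantaneous_iv_protocol",
    "lowpass",
    "bessel_lowpass_sos",
    "filter_group_delay_ms",
    "equivalent_noise_bandwidth_khz",
    "p_over_minus4",
    "read_atf",
    "write_atf",
    "read_table",
    "write_table",
]


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Epoch:
    """One constant-voltage segment of a sweep.

    ``level`` is the command voltage in mV, or ``None`` for the single epoch
    whose level varies from sweep to sweep.
    """

    level: float | None
    duration: float  # ms

    def __post_init__(self):
        if self.duration <= 0:
            raise ProtocolError(f"epoch duration must be positive, got {self.duration}")


@dataclass(frozen=True)
class VoltageProtocol:
    """Per-sweep voltage command: holding level, ordered epochs, sweep levels."""

    holding: float  # mV
    epochs: tuple[Epoch, ...]
    sweep_levels: tuple[float, ...]  # mV values taken by the varying epoch
    inter_sweep_ms: float = 0.0

    def __post_init__(self):
        if not self.epochs:
            raise ProtocolError("protocol needs at least one epoch")
        n_var = sum(1 for e in self.epochs if e.level is None)
        if n_var != 1:
            raise ProtocolError(f"exactly one epoch may vary across sweeps, found {n_var}")
        if len(self.sweep_levels) < 1:
            raise ProtocolError("protocol needs at least one sweep level")
        if self.inter_sweep_ms < 0:
            raise ProtocolError("inter-sweep interval cannot be negative")

    @property
    def n_sweeps(self) -> int:
        return len(self.sweep_levels)

    @property
    def total_duration(self) -> float:
        """Sweep duration in ms (identical for every sweep)."""
        return float(sum(e.duration for e in self.epochs))

    @property
    def varying_index(self) -> int:
        return next(i for i, e in enumerate(self.epochs) if e.level is None)

    def epoch_start(self, i: int) -> float:
        """Start time (ms) of epoch ``i`` within a sweep."""
        return float(sum(e.duration for e in self.epochs[:i]))

    def levels(self, sweep: int) -> list[float]:
        """Resolved epoch levels (mV) for one sweep."""
        v = self.sweep_levels[sweep]
        return [v if e.level is None else e.level for e in self.epochs]

    def command(self, sweep: int, t) -> np.ndarray:
        """Command voltage (mV) at times ``t`` (ms, measured from sweep start).

        Times before 0 return the holding level; epoch boundaries are
        half-open, so ``t`` exactly at a boundary belongs to the later epoch.
        """
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.full(t.shape, self.holding)
        start = 0.0
        for lvl, e in zip(self.levels(sweep), self.epochs):
            end = start + e.duration
            out[(t >= start) & (t < end)] = lvl
            start = end
        out[t >= start] = self.holding
        return out

    def command_samples(self, sweep: int, dt: float) -> np.ndarray:
        """Command voltage on the sampling grid with interval ``dt`` ms."""
        n = int(round(self.total_duration / dt))
        return self.command(sweep, (np.arange(n) + 0.5) * dt)

    def n_samples(self, dt: float) -> int:
        return int(round(self.total_duration / dt))


def _enumerate_levels(lo: float, hi: float, dV: float) -> tuple[float, ...]:
    if dV <= 0:
        raise ProtocolError(f"voltage increment dV must be positive, got {dV}")
    if hi < lo:
        raise ProtocolError(f"range end {hi} mV below start {lo} mV")
    n_steps = (hi - lo) / dV
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ProtocolError(f"({hi} − {lo}) mV is not divisible by dV = {dV} mV")
    return tuple(lo + dV * i for i in range(int(round(n_steps)) + 1))


def build_tail_protocol(
    hold: float,
    pre_from: float,
    pre_to: float,
    dV: float,
    pre_dur: float,
    tail_V: float,
    tail_dur: float,
    inter_sweep_ms: float = 0.0,
) -> VoltageProtocol:
    """Prepulse family followed by a common tail step.

    Sweeps enumerate prepulse levels from ``pre_from`` to ``pre_to``
    inclusive in steps of ``dV``; every sweep ends with the (tail_V,
    tail_dur) epoch that elicits the tail current.
    """
    levels = _enumerate_levels(pre_from, pre_to, dV)
    return VoltageProtocol(
        holding=hold,
        epochs=(Epoch(None, pre_dur), Epoch(tail_V, tail_dur)),
        sweep_levels=levels,
        inter_sweep_ms=inter_sweep_ms,
    )


def build_instantaneous_iv_protocol(
    hold: float,
    pre_V: float,
    pre_dur: float,
    test_from: float,
    test_to: float,
    dV: float,
    test_dur: float,
    inter_sweep_ms: float = 0.0,
) -> VoltageProtocol:
    """Fixed conditioning prepulse followed by a family of test voltages."""
    levels = _enumerate_levels(test_from, test_to, dV)
    return VoltageProtocol(
        holding=hold,
        epochs=(Epoch(pre_V, pre_dur), Epoch(None, test_dur)),
        sweep_levels=levels,
        inter_sweep_ms=inter_sweep_ms,
    )


# ---------------------------------------------------------------------------
# sweep container
# ---------------------------------------------------------------------------

@dataclass
class SweepSet:
    """Time-aligned current sweeps with their sampling/filtering context.

    ``traces`` is a (sweeps × samples) array in pA; ``dt`` the sampling
    interval in ms; ``filter_cutoff`` the low-pass bandwidth in kHz (None if
    unfiltered); ``meta`` free-form provenance (seed, model name, units).
    """

    dt: float
    traces: np.ndarray
    protocol: VoltageProtocol | None = None
    filter_cutoff: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        if self.dt <= 0:
            raise ParameterError(f"sampling interval must be positive, got {self.dt}")
        if self.protocol is not None:
            if self.traces.shape[0] != self.protocol.n_sweeps:
                raise AlignmentError(
                    f"{self.traces.shape[0]} traces but protocol defines "
                    f"{self.protocol.n_sweeps} sweeps"
                )
            expected = self.protocol.n_samples(self.dt)
            if abs(self.traces.shape[1] - expected) > 1:
                raise AlignmentError(
                    f"{self.traces.shape[1]} samples per sweep but protocol "
                    f"duration implies {expected}"
                )

    @property
    def n_sweeps(self) -> int:
        return self.traces.shape[0]

    @property
    def n_samples(self) -> int:
        return self.traces.shape[1]

    @property
    def fs_khz(self) -> float:
        """Sampling rate in kHz (dt is in ms)."""
        return 1.0 / self.dt

    def time(self) -> np.ndarray:
        """Sample times in ms from sweep start (bin centers)."""
        return (np.arange(self.n_samples) + 0.5) * self.dt

    def window_slice(self, t0: float, t1: float) -> slice:
        """Index slice covering the half-open time window [t0, t1) ms."""
        if not 0 <= t0 < t1 <= self.n_samples * self.dt + 1e-9:
            raise ParameterError(
                f"window [{t0}, {t1}) ms outside the sweep (0, {self.n_samples * self.dt:.3f}) ms"
            )
        return slice(int(np.floor(t0 / self.dt)), int(np.ceil(t1 / self.dt)))


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def bessel_lowpass_sos(fc_khz: float, fs_khz: float) -> np.ndarray:
    """4-pole low-pass Bessel (bilinear transform), −3 dB at ``fc_khz``.

    This is the standard digital emulation of a patch-amplifier output
    filter; DC gain is exactly 1.
    """
    if fc_khz <= 0:
        raise ParameterError(f"cutoff must be positive, got {fc_khz} kHz")
    if fc_khz >= fs_khz / 2:
        raise ParameterError(
            f"cutoff {fc_khz} kHz is at or above Nyquist ({fs_khz / 2} kHz)"
        )
    return signal.bessel(4, fc_khz, btype="low", norm="mag", fs=fs_khz, output="sos")


def filter_group_delay_ms(fc_khz: float, fs_khz: float) -> float:
    """Low-frequency group delay of the 4-pole Bessel filter, in ms.

    Steps passed through the filter emerge delayed by roughly this amount;
    isochronal/extrapolation analyses use it to locate the effective step
    onset in filtered data.
    """
    sos = bessel_lowpass_sos(fc_khz, fs_khz)
    b, a = signal.sos2tf(sos)
    w, gd = signal.group_delay((b, a), w=np.array([fc_khz * 1e-3]), fs=fs_khz)
    return float(gd[0]) / fs_khz  # samples → ms


def equivalent_noise_bandwidth_khz(fc_khz: float, fs_khz: float, n_freq: int = 4096) -> float:
    """One-sided equivalent noise bandwidth of the designed filter, in kHz.

    White noise of variance σ² at sampling rate fs emerges with variance
    σ²·ENB/(fs/2).
    """
    sos = bessel_lowpass_sos(fc_khz, fs_khz)
    w, h = signal.sosfreqz(sos, worN=n_freq, fs=fs_khz)
    return float(np.trapezoid(np.abs(h) ** 2, w))


def lowpass(rec: SweepSet, fc_khz: float) -> SweepSet:
    """Apply the 4-pole Bessel low-pass per sweep; returns a new SweepSet."""
    sos = bessel_lowpass_sos(fc_khz, rec.fs_khz)
    out = signal.sosfilt(sos, rec.traces, axis=1)
    meta = dict(rec.meta)
    meta["signal_filtered"] = True
    return replace(rec, traces=out, filter_cutoff=fc_khz, meta=meta)


# ---------------------------------------------------------------------------
# P/−4 leak subtraction
# ---------------------------------------------------------------------------

def p_over_minus4(main: SweepSet, subs: SweepSet) -> SweepSet:
    """Armstrong–Bezanilla P/−4 subtraction of linear leak and capacitance.

    ``subs`` holds four sub-sweeps per main sweep (sweep-major order), each
    driven by −P/4 of the main command.  Any strictly linear (ohmic +
    linear-capacitive) membrane response then satisfies
    main_linear = −4·mean(subs), so ``main + 4·mean(subs)`` cancels it and
    leaves the nonlinear (gating/ionic) component alone.
    """
    if subs.n_sweeps != 4 * main.n_sweeps:
        raise AlignmentError(
            f"expected {4 * main.n_sweeps} sub-sweeps (4 per main sweep), got {subs.n_sweeps}"
        )
    if subs.n_samples != main.n_samples or not np.isclose(subs.dt, main.dt):
        raise AlignmentError("sub-sweeps and main sweeps must share dt and length")
    grouped = subs.traces.reshape(main.n_sweeps, 4, main.n_samples).mean(axis=1)
    corrected = main.traces + 4.0 * grouped
    meta = dict(main.meta)
    meta["leak_subtraction"] = "P/-4"
    return replace(main, traces=corrected, meta=meta)


# ---------------------------------------------------------------------------
# ATF + table I/O
# ---------------------------------------------------------------------------

_ATF_VERSION = "1.0"


def write_atf(rec: SweepSet, path) -> None:
    """Write a SweepSet as a tab-separated Axon-Text-File.

    Layout: ``ATF<tab>1.0`` / ``<n_records><tab><n_cols>`` / optional
    ``key=value`` header records / quoted column-title line / data rows
    (time in ms, sweeps in pA, 1e-6 absolute precision).
    """
    records = []
    if rec.filter_cutoff is not None:
        records.append(f"filter_khz={rec.filter_cutoff!r}")
    if rec.meta:
        records.append("meta_json=" + json.dumps(rec.meta, default=str))
    ncols = 1 + rec.n_sweeps
    lines = [f"ATF\t{_ATF_VERSION}", f"{len(records)}\t{ncols}"]
    lines += records
    titles = ['"Time (ms)"'] + [f'"Sweep {i + 1} (pA)"' for i in range(rec.n_sweeps)]
    lines.append("\t".join(titles))
    t = rec.time()
    body = np.column_stack([t, rec.traces.T])
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        np.savetxt(fh, body, fmt="%.6f", delimiter="\t")


def read_atf(path, protocol: VoltageProtocol | None = None) -> SweepSet:
    """Read an ATF file written by :func:`write_atf` (or compatible).

    The protocol is not stored in the file; pass it to re-attach.  Malformed
    headers and ragged rows raise :class:`AtfParseError` naming the line.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or all(not ln.strip() for ln in lines):
        raise AtfParseError("empty ATF file")
    head = lines[0].split("\t")
    if head[0].strip() != "ATF":
        raise AtfParseError(f"expected 'ATF' version line, got {lines[0]!r}", line=1)
    try:
        n_rec, n_cols = (int(x) for x in lines[1].split("\t"))
    except (IndexError, ValueError):
        raise AtfParseError("expected '<n_records>\\t<n_cols>'", line=2) from None
    filter_cutoff = None
    meta: dict = {}
    for i in range(n_rec):
        raw = lines[2 + i].strip().strip('"')
        key, _, val = raw.partition("=")
        if key == "filter_khz":
            filter_cutoff = float(val)
        elif key == "meta_json":
            meta = json.loads(val)
    title_idx = 2 + n_rec
    if title_idx >= len(lines):
        raise AtfParseError("missing column-title line", line=title_idx + 1)
    data = []
    for ln_no, ln in enumerate(lines[title_idx + 1 :], start=title_idx + 2):
        if not ln.strip():
            continue
        fields = ln.split("\t")
        if len(fields) != n_cols:
            raise AtfParseError(
                f"expected {n_cols} columns, found {len(fields)}", line=ln_no
            )
        try:
            data.append([float(x) for x in fields])
        except ValueError:
            raise AtfParseError("non-numeric field", line=ln_no) from None
    if not data:
        raise AtfParseError("ATF file contains no data rows")
    arr = np.asarray(data)
    t = arr[:, 0]
    if len(t) > 1:
        steps = np.diff(t)
        dt = float(np.median(steps))
        if not np.allclose(steps, dt, rtol=0, atol=1e-4):
            raise AtfParseError("time column is not uniformly sampled")
    else:
        dt = float(2 * t[0]) if t[0] > 0 else 1.0
    return SweepSet(
        dt=dt, traces=arr[:, 1:].T, protocol=protocol,
        filter_cutoff=filter_cutoff, meta=meta,
    )


def write_table(df: pd.DataFrame, path) -> None:
    """Write a derived-curve table (CSV, no index)."""
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    """Read a derived-curve table written by :func:`write_table`."""
    return pd.read_csv(path)
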