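"""Tail-current decomposition of rectification into gating and open-pore parts.

The chain implemented here is the classical one for separating the two
sources of macroscopic rectification:

1. isochronal tail amplitudes I_t(V_pre), read at a common latency after the
   jump to the tail voltage, report the open probability reached at each
   prepulse (γ_sc is common to all tails, P_o is frozen at the jump);
2. the steady chord conductance G(V) = I/V mixes γ_sc(V) and P_o(V);
3. dividing the normalized G curve by the normalized P_o curve isolates the
   open-pore rectification γ_sc(V)/γ_sc(anchor);
4. instantaneous tail I–V (fixed +200 mV prepulse, varying test voltage)
   measures i_sc(V) directly, with the deactivation τ per test voltage;
5. normalized tail curves are fitted with a two-component Boltzmann whose
   slope factors convert to equivalent gating charges z_i = RT/(k_i F).

All curves are normalized at +200 mV by default (configurable anchor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .channel_model import (
    CONSTANTS,
    BoltzmannComponent,
    TwoBoltzmann,
    charge_from_slope,
    eval_two_boltzmann,
)
from .errors import (
    AlignmentError,
    FitError,
    NormalizationError,
    ParameterError,
)
from .recordings_io import SweepSet, filter_group_delay_ms

__all__ = [
    "CurveTable",
    "Boltzmann2Fit",
    "ExpFit",
    "TauBellFit",
    "isochronal_tails",
    "normalize_tails",
    "steady_conductance",
    "gamma_ratio",
    "instantaneous_iv",
    "fit_two_boltzmann",
    "fit_activation",
    "fit_tau_bell",
]

CURVE_LABELS = (
    "G_ratio", "Po_ratio", "tail", "tail_norm", "gamma_ratio", "isc_ratio", "tau",
)


@dataclass
class CurveTable:
    """A per-voltage derived curve with optional uncertainties.

    ``V`` must be strictly increasing; ``sem`` and ``n`` describe per-point
    scatter when several patches are pooled (sem = 0, n = 1 otherwise).
    ``flags`` records voltages excluded or annotated by the producing step.
    """

    V: np.ndarray
    y: np.ndarray
    sem: np.ndarray | None = None
    n: np.ndarray | None = None
    label: str = "tail"
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        self.V = np.asarray(self.V, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.V.ndim != 1 or self.V.shape != self.y.shape:
            raise ParameterError("V and y must be 1-D arrays of equal length")
        if np.any(np.diff(self.V) <= 0):
            raise ParameterError("V grid must be strictly increasing")
        if not np.all(np.isfinite(self.y)):
            raise ParameterError("curve values must be finite")
        self.sem = (
            np.zeros_like(self.y) if self.sem is None else np.asarray(self.sem, dtype=float)
        )
        self.n = (
            np.ones_like(self.y, dtype=int) if self.n is None else np.asarray(self.n)
        )

    def __len__(self):
        return len(self.V)

    def value_at(self, V: float) -> float:
        idx = np.flatnonzero(np.isclose(self.V, V))
        if idx.size == 0:
            raise NormalizationError(f"voltage {V} mV not on the curve grid")
        return float(self.y[idx[0]])

    def restrict(self, V_keep) -> "CurveTable":
        """Sub-curve on the voltages in ``V_keep`` (order preserved)."""
        mask = np.isin(self.V, np.asarray(V_keep, dtype=float))
        return CurveTable(
            self.V[mask], self.y[mask], self.sem[mask], self.n[mask],
            label=self.label, flags=dict(self.flags),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"V_mV": self.V, "value": self.y, "sem": self.sem, "n": self.n}
        )


# ---------------------------------------------------------------------------
# exponential fitting helpers (variable projection over τ)
# ---------------------------------------------------------------------------

def _exp_design(t, taus):
    cols = [np.ones_like(t)] + [np.exp(-t / tau) for tau in taus]
    return np.column_stack(cols)


def _fit_single_exp(t: np.ndarray, y: np.ndarray):
    """Fit y = c0 + c1·exp(−t/τ); returns (c0, c1, tau, rms).

    τ is scanned on a log grid (amplitudes solved linearly) and the best
    candidate polished by least squares; raises FitError when nothing
    converges.
    """
    span = t[-1] - t[0] if t[-1] > t[0] else 1.0
    taus = np.geomspace(span / 100.0, span * 3.0, 40)
    best = None
    for tau in taus:
        X = _exp_design(t - t[0], [tau])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        rss = float(r @ r)
        if best is None or rss < best[0]:
            best = (rss, coef, tau)
    rss, coef, tau0 = best

    def resid(p):
        c0, c1, ltau = p
        return c0 + c1 * np.exp(-(t - t[0]) / np.exp(ltau)) - y

    sol = least_squares(resid, x0=[coef[0], coef[1], np.log(tau0)], method="lm", max_nfev=2000)
    if not sol.success:
        raise FitError("single-exponential fit did not converge", best_residual=np.sqrt(rss / len(t)))
    c0, c1, ltau = sol.x
    # shift amplitude back to absolute time origin t = 0
    tau = float(np.exp(ltau))
    if t[0] / tau > 2.0:
        # decay much faster than the fit-window start: back-extrapolation
        # would amplify noise by more than e², i.e. the transient is
        # essentially unresolved before the window opens
        raise FitError("decay too fast to back-extrapolate", best_residual=np.sqrt(rss / len(t)))
    c1_at_zero = float(c1 * np.exp(t[0] / tau))
    return float(c0), c1_at_zero, tau, float(np.sqrt(np.mean(sol.fun**2)))


# ---------------------------------------------------------------------------
# tail amplitudes
# ---------------------------------------------------------------------------

def _tail_epoch(rec: SweepSet):
    prot = rec.protocol
    if prot is None:
        raise ParameterError("recording carries no protocol; cannot locate the tail epoch")
    last = prot.epochs[-1]
    if last.level is None:
        raise ParameterError("protocol must end in a common (fixed-level) tail epoch")
    onset = prot.epoch_start(len(prot.epochs) - 1)
    return onset, last


def _onset_delay(rec: SweepSet) -> float:
    """Effective step-onset shift introduced by the output filter.

    Synthetic recordings whose deterministic component bypassed the filter
    (only the seal noise is band-limited) carry ``signal_filtered: False``
    in their metadata and need no shift.
    """
    if rec.filter_cutoff is None or rec.meta.get("signal_filtered", True) is False:
        return 0.0
    return filter_group_delay_ms(rec.filter_cutoff, rec.fs_khz)


def isochronal_tails(
    rec: SweepSet,
    t_iso: float = 0.5,
    avg_window: float = 0.1,
    mode: str = "point",
    blank: float = 0.1,
    fit_window: float | None = None,
) -> CurveTable:
    """Tail-current amplitude per sweep versus prepulse voltage.

    ``mode='point'`` reads every sweep at the same latency ``t_iso`` (ms
    after tail onset, filter delay accounted for), averaging over
    ``avg_window`` ms centered on it.  ``mode='peak'`` takes the extreme
    excursion after the blanking window.  ``mode='extrapolate'`` fits a
    single exponential past ``blank`` and back-extrapolates to the onset —
    the estimate of the instantaneous tail amplitude, immune to the decay
    during the first samples.
    """
    onset, tail = _tail_epoch(rec)
    onset_eff = onset + _onset_delay(rec)
    t = rec.time()
    amps = np.empty(rec.n_sweeps)
    flags: dict = {}
    if mode == "point":
        if not 0 <= t_iso <= tail.duration:
            raise ParameterError(
                f"isochronal latency {t_iso} ms outside the tail epoch (0–{tail.duration} ms)"
            )
        lo = onset_eff + max(t_iso - avg_window / 2.0, 0.0)
        hi = min(onset_eff + t_iso + avg_window / 2.0, onset + tail.duration)
        hi = max(hi, lo + rec.dt)
        sel = (t >= lo) & (t < hi)
        if not np.any(sel):
            raise ParameterError("isochronal averaging window contains no samples")
        amps = rec.traces[:, sel].mean(axis=1)
    elif mode == "peak":
        sel = (t >= onset_eff + blank) & (t < onset + tail.duration)
        seg = rec.traces[:, sel]
        idx = np.argmax(np.abs(seg), axis=1)
        amps = seg[np.arange(rec.n_sweeps), idx]
    elif mode == "extrapolate":
        win = fit_window if fit_window is not None else tail.duration - blank
        sel = (t >= onset_eff + blank) & (t < onset_eff + blank + win)
        tt = t[sel] - onset_eff
        for s in range(rec.n_sweeps):
            try:
                c0, c1, _tau, _ = _fit_single_exp(tt, rec.traces[s, sel])
                amps[s] = c0 + c1
            except FitError:
                amps[s] = rec.traces[s, sel][0]
                flags[rec.protocol.sweep_levels[s]] = "exp-fit failed; first-sample fallback"
    else:
        raise ParameterError(f"unknown tail mode {mode!r}")
    V = np.asarray(rec.protocol.sweep_levels, dtype=float)
    order = np.argsort(V)
    return CurveTable(V[order], amps[order], label="tail", flags=flags)


def normalize_tails(tails: CurveTable, mode: str = "minsub", anchor: float = 200.0) -> CurveTable:
    """Normalize tail amplitudes to the anchor voltage.

    ``minsub``: (I_t − I_min)/(I_anchor − I_min) — 0 at the smallest tail,
    1 at the anchor; invariant to gain and offset of the raw amplitudes.
    ``plain``: I_t/I_anchor — 1 at the anchor.
    """
    y = tails.y
    idx = np.flatnonzero(np.isclose(tails.V, anchor))
    if idx.size == 0:
        raise NormalizationError(f"anchor voltage {anchor} mV absent from the curve")
    ia = idx[0]
    if mode == "plain":
        if y[ia] == 0:
            raise NormalizationError("anchor amplitude is zero; cannot normalize")
        out = y / y[ia]
    elif mode == "minsub":
        # orientation: the anchor should carry the largest amplitude
        s = 1.0 if y[ia] >= np.mean(y) else -1.0
        a = s * y
        rng = a[ia] - a.min()
        if rng == 0:
            raise NormalizationError("flat tail curve; min-subtracted normalization undefined")
        out = (a - a.min()) / rng
    else:
        raise ParameterError(f"unknown normalization mode {mode!r}")
    return CurveTable(tails.V, out, tails.sem, tails.n, label="tail_norm", flags=dict(tails.flags))


# ---------------------------------------------------------------------------
# conductance and the γ decomposition
# ---------------------------------------------------------------------------

def steady_conductance(
    rec: SweepSet, window: float = 10.0, anchor: float = 200.0
) -> CurveTable:
    """Fractional steady chord conductance G(V)/G(anchor) from the prepulses.

    G(V) = mean steady current over the last ``window`` ms of the varying
    (prepulse) epoch divided by V; the V = 0 point is dropped.
    """
    prot = rec.protocol
    if prot is None:
        raise ParameterError("recording carries no protocol")
    j = prot.varying_index
    start = prot.epoch_start(j)
    end = start + prot.epochs[j].duration
    if window <= 0 or window > prot.epochs[j].duration:
        raise ParameterError(
            f"steady window {window} ms overruns the {prot.epochs[j].duration} ms prepulse epoch"
        )
    t = rec.time()
    sel = (t >= end - window) & (t < end)
    V = np.asarray(prot.sweep_levels, dtype=float)
    mean_i = rec.traces[:, sel].mean(axis=1)
    keep = V != 0.0
    G = mean_i[keep] / V[keep]
    Vk = V[keep]
    order = np.argsort(Vk)
    curve = CurveTable(Vk[order], G[order], label="G_ratio")
    ga = curve.value_at(anchor)
    if ga == 0:
        raise NormalizationError("anchor conductance is zero")
    curve.y = curve.y / ga
    return curve


def gamma_ratio(G: CurveTable, Po: CurveTable, floor: float = 0.01) -> CurveTable:
    """Open-pore rectification γ_sc(V)/γ_sc(anchor) = (G ratio)/(P_o ratio).

    Points where the P_o ratio falls below ``floor`` are masked (dropped and
    recorded in ``flags``) rather than divided, to avoid noise blow-up.
    """
    if len(G) != len(Po) or not np.allclose(G.V, Po.V):
        raise AlignmentError("G and P_o curves must share the same voltage grid")
    ok = np.abs(Po.y) >= floor
    flags = {float(v): f"P_o ratio below floor {floor}" for v in G.V[~ok]}
    return CurveTable(G.V[ok], G.y[ok] / Po.y[ok], label="gamma_ratio", flags=flags)


def instantaneous_iv(
    rec: SweepSet, blank: float = 0.15, anchor: float = 200.0, fit_window: float | None = None
):
    """Instantaneous I–V and deactivation kinetics from a tail family.

    The protocol must hold a fixed depolarized prepulse and vary the test
    (final) voltage.  Per test voltage a single exponential
    I(t) = I_ss + A·exp(−t/τ) is fitted past the blanking window; the
    back-extrapolated amplitude at the jump gives the instantaneous current
    (∝ i_sc at that voltage, P_o frozen at the prepulse value) and τ the
    deactivation time constant.  Returns ``(isc_ratio, tau)`` curve tables;
    per-point fit failures are flagged, never fatal.
    """
    prot = rec.protocol
    if prot is None:
        raise ParameterError("recording carries no protocol")
    if prot.varying_index != len(prot.epochs) - 1:
        raise ParameterError("instantaneous I–V needs the varying (test) epoch to be the final one")
    tail = prot.epochs[-1]
    onset = prot.epoch_start(len(prot.epochs) - 1)
    onset_eff = onset + _onset_delay(rec)
    t = rec.time()
    win = fit_window if fit_window is not None else tail.duration - blank
    sel = (t >= onset_eff + blank) & (t < onset_eff + blank + win)
    tt = t[sel] - onset_eff
    V = np.asarray(rec.protocol.sweep_levels, dtype=float)
    i0 = np.full(V.shape, np.nan)
    tau = np.full(V.shape, np.nan)
    flags: dict = {}
    for s in range(rec.n_sweeps):
        y = rec.traces[s, sel]
        try:
            c0, c1, tau_s, _ = _fit_single_exp(tt, y)
            i0[s] = c0 + c1
            tau[s] = tau_s
        except (FitError, np.linalg.LinAlgError):
            flags[float(V[s])] = "exponential fit failed"
    ok = np.isfinite(i0)
    order = np.argsort(V[ok])
    Vok = V[ok][order]
    iv = CurveTable(Vok, i0[ok][order], label="isc_ratio", flags=flags)
    anchor_val = iv.value_at(anchor)
    if anchor_val == 0:
        raise NormalizationError("anchor instantaneous current is zero")
    iv.y = iv.y / anchor_val
    tau_curve = CurveTable(Vok, tau[ok][order], label="tau", flags=dict(flags))
    return iv, tau_curve


# ---------------------------------------------------------------------------
# two-component Boltzmann fitting
# ---------------------------------------------------------------------------

@dataclass
class Boltzmann2Fit:
    """Result of a two-component Boltzmann fit.

    Component 1 is the one with the smaller V_mid; z_i = RT/(k_i F).
    ``se`` maps parameter names to asymptotic standard errors; ``degenerate``
    is set when the two components cannot be told apart (single-Boltzmann
    data, weight at a bound, or an exploded covariance).
    """

    A: float
    V_mid1: float
    k1: float
    V_mid2: float
    k2: float
    z1: float
    z2: float
    se: dict
    rmse: float
    converged: bool
    degenerate: bool
    cov: np.ndarray | None = None
    T: float = CONSTANTS.T

    def model(self) -> TwoBoltzmann:
        return TwoBoltzmann(
            self.A,
            BoltzmannComponent(self.V_mid1, self.k1),
            BoltzmannComponent(self.V_mid2, self.k2),
        )

    def __str__(self):
        lines = [
            "two-component Boltzmann fit"
            + (" [DEGENERATE]" if self.degenerate else ""),
            f"  A      = {self.A:8.4f} ± {self.se.get('A', float('nan')):.4f}",
            f"  V_mid1 = {self.V_mid1:8.2f} ± {self.se.get('V_mid1', float('nan')):.2f} mV"
            f"   (z1 = {self.z1:.2f})",
            f"  V_mid2 = {self.V_mid2:8.2f} ± {self.se.get('V_mid2', float('nan')):.2f} mV"
            f"   (z2 = {self.z2:.2f})",
            f"  rmse   = {self.rmse:.4g}",
        ]
        return "\n".join(lines)


def _tb_eval(p, V):
    A, v1, k1, v2, k2 = p
    return eval_two_boltzmann(
        V, TwoBoltzmann(A, BoltzmannComponent(v1, k1), BoltzmannComponent(v2, k2))
    )


def fit_two_boltzmann(
    curve: CurveTable,
    init: tuple | None = None,
    T: float = CONSTANTS.T,
) -> Boltzmann2Fit:
    """Weighted least-squares fit of A·B1(V) + (1−A)·B2(V) to a normalized curve.

    Needs at least 8 points.  Weights are 1/sem where per-point SEMs from
    pooled patches are available (n > 1), unweighted otherwise.  Several
    starting points are tried; the best solution is returned with parameter
    standard errors from the Jacobian.  Raises FitError (carrying the best
    residual) if no start converges.
    """
    if len(curve) < 8:
        raise ParameterError(f"need at least 8 points to fit, got {len(curve)}")
    V, y = curve.V, curve.y
    use_w = np.all(curve.n > 1) and np.all(curve.sem > 0)
    w = 1.0 / curve.sem if use_w else np.ones_like(y)

    lo = np.array([0.0, -500.0, 0.5, -500.0, 0.5])
    hi = np.array([1.0, 500.0, 300.0, 500.0, 300.0])

    def resid(p):
        return (_tb_eval(p, V) - y) * w

    starts = []
    if init is not None:
        starts.append(np.asarray(init, dtype=float))
    vspan = V[-1] - V[0]
    for A0 in (0.3, 0.5, 0.7):
        for f1, f2 in ((0.25, 0.75), (0.1, 0.6), (0.4, 0.9)):
            starts.append(
                np.array([A0, V[0] + f1 * vspan, 20.0, V[0] + f2 * vspan, 25.0])
            )
    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi), max_nfev=5000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        best_res = float(np.sqrt(2 * best.cost / len(V))) if best is not None else None
        raise FitError("two-Boltzmann fit failed from every start", best_residual=best_res)

    p = best.x
    # order components by V_mid (component 1 = smaller)
    if p[1] > p[3]:
        p = np.array([1.0 - p[0], p[3], p[4], p[1], p[2]])
    dof = max(len(V) - 5, 1)
    s2 = 2 * best.cost / dof
    J = best.jac
    names = ["A", "V_mid1", "k1", "V_mid2", "k2"]
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        se_vals = np.sqrt(np.clip(np.diag(cov), 0, None))
        cond = np.linalg.cond(J.T @ J)
    except np.linalg.LinAlgError:
        cov = None
        se_vals = np.full(5, np.nan)
        cond = np.inf
    se = dict(zip(names, se_vals))
    degenerate = bool(
        cond > 1e10
        or p[0] < 0.02
        or p[0] > 0.98
        or abs(p[3] - p[1]) < 0.5 * max(p[2], p[4])
        or not np.all(np.isfinite(se_vals))
    )
    return Boltzmann2Fit(
        A=float(p[0]), V_mid1=float(p[1]), k1=float(p[2]),
        V_mid2=float(p[3]), k2=float(p[4]),
        z1=charge_from_slope(p[2], T), z2=charge_from_slope(p[4], T),
        se=se, rmse=float(np.sqrt(np.mean((_tb_eval(p, V) - y) ** 2))),
        converged=True, degenerate=degenerate, cov=cov, T=T,
    )


# ---------------------------------------------------------------------------
# activation kinetics
# ---------------------------------------------------------------------------

@dataclass
class ExpFit:
    """Double-exponential fit of an activation time course (τ_f < τ_s)."""

    tau_f: float
    tau_s: float
    amp_f: float
    amp_s: float
    offset: float
    rmse: float
    flags: tuple = ()


def fit_activation(t: np.ndarray, i: np.ndarray, n_exp: int = 2) -> ExpFit:
    """Fit I(t) = I_ss + a_f·e^(−t/τ_f) + a_s·e^(−t/τ_s) to one trace.

    Amplitudes are solved linearly for each candidate (τ_f, τ_s) pair
    (variable projection), then the winner is polished.  The fast/slow
    ordering τ_f < τ_s is enforced.  Flags: ``tau-overlap`` when
    τ_s/τ_f < 3 (poor identifiability), ``single-exponential`` when the
    second amplitude is negligible.
    """
    t = np.asarray(t, dtype=float)
    i = np.asarray(i, dtype=float)
    if n_exp == 1:
        c0, c1, tau, rmse = _fit_single_exp(t, i)
        return ExpFit(tau, tau, c1, 0.0, c0, rmse, flags=("single-exponential",))
    if n_exp != 2:
        raise ParameterError("only n_exp in {1, 2} is supported")
    span = max(t[-1] - t[0], 1e-6)
    grid = np.geomspace(span / 200.0, span * 2.0, 25)
    t0 = t - t[0]
    best = None
    for a_idx in range(len(grid)):
        for b_idx in range(a_idx + 1, len(grid)):
            X = _exp_design(t0, [grid[a_idx], grid[b_idx]])
            coef, *_ = np.linalg.lstsq(X, i, rcond=None)
            r = i - X @ coef
            rss = float(r @ r)
            if best is None or rss < best[0]:
                best = (rss, coef, grid[a_idx], grid[b_idx])
    _, coef, tf0, ts0 = best

    def resid(p):
        c0, cf, cs, ltf, lts = p
        return c0 + cf * np.exp(-t0 / np.exp(ltf)) + cs * np.exp(-t0 / np.exp(lts)) - i

    sol = least_squares(
        resid, x0=[coef[0], coef[1], coef[2], np.log(tf0), np.log(ts0)],
        method="lm", max_nfev=5000,
    )
    c0, cf, cs, ltf, lts = sol.x
    tf, ts = float(np.exp(ltf)), float(np.exp(lts))
    if tf > ts:
        tf, ts, cf, cs = ts, tf, cs, cf
    flags = []
    if ts / max(tf, 1e-12) < 3.0:
        flags.append("tau-overlap")
    if abs(cs) < 1e-3 * max(abs(cf), 1e-12) or abs(cf) < 1e-3 * max(abs(cs), 1e-12):
        flags.append("single-exponential")
    rmse = float(np.sqrt(np.mean(sol.fun**2)))
    return ExpFit(tf, ts, float(cf), float(cs), float(c0), rmse, flags=tuple(flags))


@dataclass
class TauBellFit:
    """Fit of a bell-shaped τ(V) = 1/(α(V)+β(V)) with a symmetric charge split."""

    a0: float
    b0: float
    z_eq: float
    rmse: float

    @property
    def V_mid(self) -> float:
        """Voltage of equal forward/backward rates (τ maximum)."""
        vt = CONSTANTS.thermal_mV
        return vt / self.z_eq * np.log(self.b0 / self.a0)


def fit_tau_bell(curve: CurveTable, T: float = CONSTANTS.T) -> TauBellFit:
    """Recover (a0, b0, z_eq) from a τ(V) curve.

    Model: τ(V) = 1/(a0·e^(z·FV/2RT) + b0·e^(−z·FV/2RT)) — the equivalent
    charge is split evenly between the forward and backward rates.  Fitting
    is done on log τ, appropriate for multiplicative scatter.  Needs ≥ 5
    voltages.
    """
    if len(curve) < 5:
        raise ParameterError(f"bell fit needs at least 5 voltages, got {len(curve)}")
    V, tau = curve.V, curve.y
    if np.any(tau <= 0):
        raise ParameterError("time constants must be positive")
    vt = 1000.0 * CONSTANTS.R * T / CONSTANTS.F
    ly = np.log(tau)

    def resid(p):
        la0, lb0, z = p
        rate = np.exp(la0 + z * V / (2 * vt)) + np.exp(lb0 - z * V / (2 * vt))
        return -np.log(rate) - ly

    best = None
    for z0 in (0.3, 0.9, 2.0):
        tau_max = float(np.max(tau))
        x0 = [np.log(0.5 / tau_max), np.log(0.5 / tau_max), z0]
        sol = least_squares(resid, x0, bounds=([-20, -20, 0.0], [20, 20, 15.0]), max_nfev=5000)
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise FitError("τ(V) bell fit failed")
    la0, lb0, z = best.x
    return TauBellFit(
        a0=float(np.exp(la0)), b0=float(np.exp(lb0)), z_eq=float(z),
        rmse=float(np.sqrt(np.mean(best.fun**2))),
    )
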