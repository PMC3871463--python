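"""Stationary noise analysis and amplitude-histogram channel counting.

For a homogeneous population of N two-state channels opening to a single
conductance level, the stationary current variance relates to the mean as

    σ² = i_sc·I − I²/N,   hence   σ²/I = i_sc·(1 − P_o),

so the variance-to-mean ratio measured at each voltage (after subtracting
the background recorded without agonist) can be compared against the
i_sc(1−P_o) prediction built from the instantaneous I–V and tail-current
curves, and inverted for the absolute open probability.

The module also bounds the contribution of open-channel noise σ_o (fast,
unresolved fluctuations of the open pore): with σ_e² = N·P_o·σ_o² on top of
the gating variance σ² = N·i_sc²·P_o(1−P_o), the fractional r.m.s. increase
depends only on σ_o/i_sc and P_o.

All-point amplitude histograms of near-single-channel patches are fitted
with Gaussian mixtures; a patch with c channels needs c+1 components, so
the selected component count minus one estimates the channel count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .channel_model import ChannelModel
from .errors import AlignmentError, ParameterError
from .recordings_io import SweepSet, bessel_lowpass_sos
from .tail_analysis import CurveTable
from scipy import signal as _signal

__all__ = [
    "NoiseTable",
    "HistogramFit",
    "variance_to_mean",
    "predicted_ratio",
    "absolute_po_from_noise",
    "open_noise_inflation",
    "amplitude_histogram",
    "fit_gaussian_mixture",
    "count_channels_from_histogram",
]


@dataclass
class NoiseTable:
    """Per-voltage stationary-noise summary.

    ``ratio`` = (var_cgmp − var_seal)/I_mean in pA; points where |I_mean|
    falls below the floor are masked (NaN ratio, listed in ``masked``).
    """

    V: np.ndarray
    I_mean: np.ndarray
    var_cgmp: np.ndarray
    var_seal: np.ndarray
    ratio: np.ndarray
    masked: tuple = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "V_mV": self.V,
                "I_mean_pA": self.I_mean,
                "var_cgmp_pA2": self.var_cgmp,
                "var_seal_pA2": self.var_seal,
                "ratio_pA": self.ratio,
            }
        )

    def curve(self) -> CurveTable:
        """Unmasked σ²/I points as a CurveTable (for overlays and fits)."""
        ok = np.isfinite(self.ratio)
        return CurveTable(self.V[ok], self.ratio[ok], label="tau")


def _steady_window(rec: SweepSet, window):
    prot = rec.protocol
    if prot is None:
        raise ParameterError("recording carries no protocol")
    j = prot.varying_index
    end = prot.epoch_start(j) + prot.epochs[j].duration
    if isinstance(window, tuple):
        t0, t1 = window
    else:
        t0, t1 = end - float(window), end
    t = rec.time()
    sel = (t >= t0) & (t < t1)
    if not np.any(sel):
        raise ParameterError("stationary window contains no samples")
    return sel


def variance_to_mean(
    rec_cgmp: SweepSet,
    rec_seal: SweepSet,
    window=50.0,
    floor: float = 1.0,
    subtraction: str = "variance",
) -> NoiseTable:
    """σ²/I per voltage from paired cGMP and no-cGMP (seal) recordings.

    ``window`` is either a length (ms, taken at the end of the varying
    epoch) or an explicit (t0, t1) pair.  Background subtraction is on the
    variances by default (independent sources add in quadrature);
    ``subtraction='rms'`` reproduces the literal r.m.s. difference
    (σ_cGMP − σ_seal)² instead.
    """
    if rec_cgmp.n_sweeps != rec_seal.n_sweeps:
        raise AlignmentError("cGMP and seal recordings must have matched sweep counts")
    if subtraction not in ("variance", "rms"):
        raise ParameterError(f"unknown subtraction mode {subtraction!r}")
    sel = _steady_window(rec_cgmp, window)
    seg_c = rec_cgmp.traces[:, sel]
    seg_s = rec_seal.traces[:, sel]
    I_mean = seg_c.mean(axis=1) - seg_s.mean(axis=1)
    var_c = seg_c.var(axis=1, ddof=1)
    var_s = seg_s.var(axis=1, ddof=1)
    if subtraction == "variance":
        var_net = var_c - var_s
    else:
        var_net = np.square(np.sqrt(var_c) - np.sqrt(var_s))
    V = np.asarray(rec_cgmp.protocol.sweep_levels, dtype=float)
    ratio = np.where(np.abs(I_mean) >= floor, var_net / I_mean, np.nan)
    masked = tuple(float(v) for v in V[np.abs(I_mean) < floor])
    order = np.argsort(V)
    return NoiseTable(
        V=V[order], I_mean=I_mean[order], var_cgmp=var_c[order],
        var_seal=var_s[order], ratio=ratio[order], masked=masked,
    )


def predicted_ratio(model: ChannelModel, V_grid) -> CurveTable:
    """Expected σ²/I curve i_sc(V)·(1 − P_o(V)) on a voltage grid, in pA."""
    V = np.sort(np.asarray(V_grid, dtype=float))
    return CurveTable(V, model.isc(V) * (1.0 - model.po(V)), label="tau")


def absolute_po_from_noise(ratio: float, i_sc: float):
    """Absolute open probability from the noise ratio: P_o = 1 − (σ²/I)/i_sc.

    Clamped to [0, 1]; returns ``(P_o, out_of_range)`` where the flag marks
    raw values outside the unit interval (inconsistent ratio/i_sc pairing).
    """
    if i_sc == 0:
        raise ParameterError("single-channel current i_sc must be non-zero")
    raw = 1.0 - ratio / i_sc
    return float(np.clip(raw, 0.0, 1.0)), bool(raw < 0 or raw > 1)


def open_noise_inflation(sigma_o_over_i: float, Po: float) -> float:
    """Fractional r.m.s. increase caused by open-channel noise.

    σ_tot² = σ² + σ_e² with σ² = N·i_sc²·P_o(1−P_o) and σ_e² = N·P_o·σ_o²;
    N and i_sc cancel, leaving sqrt(1 + (σ_o/i_sc)²/(1−P_o)) − 1.
    Monotone increasing in both arguments; vanishes with σ_o.
    """
    if sigma_o_over_i < 0:
        raise ParameterError("sigma_o/i_sc must be non-negative")
    if not 0.0 <= Po < 1.0:
        raise ParameterError(
            f"open probability must lie in [0, 1); at Po = 1 gating noise vanishes "
            f"and the ratio is undefined (got {Po})"
        )
    return float(np.sqrt(1.0 + sigma_o_over_i**2 / (1.0 - Po)) - 1.0)


# ---------------------------------------------------------------------------
# amplitude histograms
# ---------------------------------------------------------------------------

def amplitude_histogram(
    rec: SweepSet,
    bin_width: float | None = None,
    refilter_khz: float | None = 1.0,
    decimate_to_khz: float | None = None,
):
    """All-point amplitude histogram of a near-single-channel recording.

    The trace is optionally refiltered offline (1 kHz by default, the
    standard choice for resolving unitary levels) and then decimated to
    twice the refilter bandwidth — the Nyquist rate of the retained signal
    — so that the samples handed to likelihood-based mixture fitting are
    approximately independent.  ``bin_width`` defaults to a fifth of the
    trace s.d.  Returns ``(counts, bin_edges, samples)``.
    """
    if rec.traces.size == 0:
        raise ParameterError("empty recording")
    x = rec.traces
    refiltered = refilter_khz is not None and (
        rec.filter_cutoff is None or refilter_khz < rec.filter_cutoff
    )
    if refiltered:
        sos = bessel_lowpass_sos(refilter_khz, rec.fs_khz)
        x = _signal.sosfilt(sos, x, axis=1)
    x = x.ravel()
    if decimate_to_khz is None and refiltered:
        decimate_to_khz = 2.0 * refilter_khz
    if decimate_to_khz is not None and rec.fs_khz > decimate_to_khz:
        step = int(round(rec.fs_khz / decimate_to_khz))
        x = x[::step]
    if bin_width is None:
        sd = float(np.std(x))
        bin_width = sd / 5.0 if sd > 0 else 0.1
    edges = np.arange(x.min() - bin_width, x.max() + 2 * bin_width, bin_width)
    counts, edges = np.histogram(x, bins=edges)
    return counts, edges, x


@dataclass
class HistogramFit:
    """Gaussian-mixture description of an all-point histogram.

    A patch holding c identical channels visits c+1 current levels
    (0…c channels open), so ``channel_count = n_components − 1``, where
    ``n_components`` counts *resolved* levels: mixture components whose
    means sit within the level-resolution limit of each other describe the
    same conductance level and are merged before counting.
    """

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    n_components: int
    channel_count: int
    bic: float

    def __str__(self):
        rows = "\n".join(
            f"  component {i + 1}: mean = {m:7.3f} pA, sd = {s:6.3f} pA, weight = {w:.3f}"
            for i, (m, s, w) in enumerate(zip(self.means, self.sds, self.weights))
        )
        return (
            f"Gaussian mixture: {self.n_components} components "
            f"→ {self.channel_count} channel(s)\n{rows}"
        )


def fit_gaussian_mixture(
    samples: np.ndarray,
    n_components: int | None = None,
    max_components: int = 4,
    min_weight: float = 0.05,
    seed: int = 0,
) -> HistogramFit:
    """Maximum-likelihood Gaussian mixture on amplitude samples.

    With ``n_components=None`` the count is selected by BIC over
    1..``max_components``, restricted to solutions whose components all
    carry at least ``min_weight`` of the data: a conductance level occupied
    for a vanishing fraction of the record is indistinguishable from the
    thin bridge of filter-smeared transition samples between real levels,
    which must not be counted as a channel.  Components are reported sorted
    by mean.
    """
    x = np.asarray(samples, dtype=float).reshape(-1, 1)
    if x.size < 10:
        raise ParameterError("too few samples for a mixture fit")
    candidates = [n_components] if n_components else range(1, max_components + 1)
    best = None
    fallback = None
    for k in candidates:
        gm = GaussianMixture(n_components=k, random_state=seed, n_init=3).fit(x)
        bic = gm.bic(x)
        if fallback is None or bic < fallback[0]:
            fallback = (bic, gm, k)
        if n_components is None and k > 1 and gm.weights_.min() < min_weight:
            continue
        if best is None or bic < best[0]:
            best = (bic, gm, k)
    bic, gm, k = best if best is not None else fallback
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.ravel()[order])
    weights = gm.weights_[order]
    if n_components is None:
        means, sds, weights = _merge_unresolved(means, sds, weights)
    k_eff = len(means)
    return HistogramFit(
        means=means, sds=sds, weights=weights,
        n_components=k_eff,
        channel_count=k_eff - 1,
        bic=float(bic),
    )


def _merge_unresolved(means, sds, weights, resolution_sd: float = 2.0):
    """Merge mixture components that describe a single conductance level.

    Two Gaussians whose means differ by less than ``resolution_sd`` times
    the wider s.d. are not separable current levels (the likelihood happily
    splits a skewed level into overlapping components); they are pooled
    into one component with matched moments.
    """
    means, sds, weights = list(means), list(sds), list(weights)
    i = 0
    while i < len(means) - 1:
        if abs(means[i + 1] - means[i]) < resolution_sd * max(sds[i], sds[i + 1]):
            w = weights[i] + weights[i + 1]
            mu = (weights[i] * means[i] + weights[i + 1] * means[i + 1]) / w
            var = (
                weights[i] * (sds[i] ** 2 + (means[i] - mu) ** 2)
                + weights[i + 1] * (sds[i + 1] ** 2 + (means[i + 1] - mu) ** 2)
            ) / w
            means[i], sds[i], weights[i] = mu, np.sqrt(var), w
            del means[i + 1], sds[i + 1], weights[i + 1]
        else:
            i += 1
    return np.asarray(means), np.asarray(sds), np.asarray(weights)


def count_channels_from_histogram(rec: SweepSet, seed: int = 0, **kwargs) -> HistogramFit:
    """Convenience chain: amplitude_histogram → BIC-selected mixture fit."""
    _, _, samples = amplitude_histogram(rec, **kwargs)
    return fit_gaussian_mixture(samples, seed=seed)
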