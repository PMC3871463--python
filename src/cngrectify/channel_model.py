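"""Parametric laws of a CNG-type channel.

This module houses everything both the simulator and the fitting routines
need to know about a channel:

* the equilibrium open-probability law — a weighted sum of two Boltzmann
  sigmoids, the standard description when two distinct voltage-dependent
  transitions shape activation;
* the conversion between a Boltzmann slope factor ``k`` (mV) and the
  equivalent gating charge ``z`` (elementary charges), z = RT/(kF);
* a two-state relaxation law α(V), β(V) giving the activation/deactivation
  time constant τ(V) = 1/(α+β);
* an open-pore current law i_sc(V) with a sigmoidal chord conductance,
  a parametric stand-in for the empirical single-channel rectification of
  the different permeant ions (Li⁺ … Cs⁺, MA⁺/DMA⁺/EA⁺).

Voltages are millivolts throughout; slope factors are stored in mV and all
RT/F arithmetic converts to volts internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .errors import ParameterError

__all__ = [
    "Constants",
    "CONSTANTS",
    "BoltzmannComponent",
    "TwoBoltzmann",
    "RateLaw",
    "PermeationLaw",
    "ChannelModel",
    "eval_boltzmann",
    "eval_two_boltzmann",
    "charge_from_slope",
    "slope_from_charge",
    "relaxation",
    "open_pore_current",
]


@dataclass(frozen=True)
class Constants:
    """Physical constants used everywhere.

    R and F are the gas and Faraday constants; ``e0`` the elementary charge
    (1.6e-19 C); ``T`` the absolute temperature, 295 K by default (room
    temperature recording).  ``thermal_mV`` = RT/F in millivolts evaluates
    to ~25.4 mV at 295 K.
    """

    R: float = 8.31446261815324  # J mol^-1 K^-1
    F: float = 96485.33212331  # C mol^-1
    e0: float = 1.6e-19  # C
    T: float = 295.0  # K

    def __post_init__(self):
        if min(self.R, self.F, self.e0, self.T) <= 0:
            raise ParameterError("all physical constants must be strictly positive")

    @property
    def thermal_mV(self) -> float:
        """RT/F expressed in mV."""
        return 1000.0 * self.R * self.T / self.F


CONSTANTS = Constants()


def _thermal_mV(T: float) -> float:
    if T <= 0:
        raise ParameterError(f"temperature must be positive, got {T}")
    return 1000.0 * CONSTANTS.R * T / CONSTANTS.F


@dataclass(frozen=True)
class BoltzmannComponent:
    """One sigmoid activation component: value = 1/(1+exp((V_mid − V)/k)).

    ``k`` may be negative (activation by hyperpolarization); it must not be 0.
    """

    V_mid: float  # mV, half-activation voltage
    k: float  # mV, slope factor

    def __post_init__(self):
        if self.k == 0 or not np.isfinite(self.k) or not np.isfinite(self.V_mid):
            raise ParameterError(f"invalid Boltzmann component (V_mid={self.V_mid}, k={self.k})")

    def z(self, T: float = CONSTANTS.T) -> float:
        """Equivalent charge of this component, z = RT/(|k|F)."""
        return charge_from_slope(abs(self.k), T)


@dataclass(frozen=True)
class TwoBoltzmann:
    """Weighted sum of two Boltzmann components: A·B1(V) + (1−A)·B2(V)."""

    A: float
    c1: BoltzmannComponent
    c2: BoltzmannComponent

    def __post_init__(self):
        if not 0.0 <= self.A <= 1.0:
            raise ParameterError(f"component weight A must lie in [0, 1], got {self.A}")


@dataclass(frozen=True)
class RateLaw:
    """Exponentially voltage-dependent forward/backward rates (Eyring form).

    α(V) = a0·exp(za·FV/RT), β(V) = b0·exp(−zb·FV/RT); rates in ms⁻¹,
    equivalent charges in e0 units.  τ(V) = 1/(α+β) is bell-shaped with a
    single maximum whenever za+zb > 0.
    """

    a0: float  # ms^-1, forward rate at 0 mV
    za: float  # e0, forward equivalent charge
    b0: float  # ms^-1, backward rate at 0 mV
    zb: float  # e0, backward equivalent charge

    def __post_init__(self):
        if self.a0 <= 0 or self.b0 <= 0:
            raise ParameterError("zero-voltage rates a0, b0 must be positive")
        if self.za < 0 or self.zb < 0:
            raise ParameterError("equivalent charges za, zb must be non-negative")


@dataclass(frozen=True)
class PermeationLaw:
    """Open-pore current law with a sigmoidal chord conductance.

    γ(V) = g_plus + (g_minus − g_plus)/(1 + exp(V/V_s)) interpolates between
    the limiting chord conductances at depolarized (g_plus) and
    hyperpolarized (g_minus) voltages; i_sc(V) = γ(V)·V (pS·mV → fA,
    reported in pA).  In symmetrical solutions i_sc(0) = 0 by construction.
    """

    g_plus: float  # pS, limiting chord conductance at depolarized V
    g_minus: float  # pS, limiting chord conductance at hyperpolarized V
    V_s: float  # mV, transition steepness

    def __post_init__(self):
        if self.g_plus <= 0 or self.g_minus <= 0:
            raise ParameterError("limiting conductances must be positive")
        if self.V_s == 0:
            raise ParameterError("V_s must be non-zero")


@dataclass(frozen=True)
class ChannelModel:
    """A complete channel: gating equilibrium, kinetics, permeation, count.

    ``sigma_o_over_i`` is the open-channel noise ratio σ_o/i_sc (≈0.1 for
    CNGA1 at +100 mV, independent of the permeant ion).
    """

    po_law: TwoBoltzmann
    rate_law: RateLaw
    perm: PermeationLaw
    N: int = 1
    sigma_o_over_i: float = 0.0
    name: str = "custom"
    T: float = CONSTANTS.T

    def __post_init__(self):
        if int(self.N) != self.N or self.N < 0:
            raise ParameterError(f"channel count N must be a non-negative integer, got {self.N}")
        if self.sigma_o_over_i < 0:
            raise ParameterError("sigma_o_over_i must be non-negative")

    # -- convenience laws ------------------------------------------------
    def po(self, V):
        """Equilibrium open probability at V (mV)."""
        return eval_two_boltzmann(V, self.po_law)

    def isc(self, V):
        """Single open-channel current at V (pA)."""
        return open_pore_current(V, self.perm)

    def gamma(self, V):
        """Chord conductance of the open pore at V (pS)."""
        p = self.perm
        return p.g_plus + (p.g_minus - p.g_plus) * expit(-np.asarray(V, float) / p.V_s)

    def tau(self, V):
        """Relaxation time constant τ(V) = 1/(α+β) in ms."""
        return relaxation(V, self.rate_law, T=self.T)[2]

    def noise_ratio(self, V):
        """Stationary gating-noise prediction σ²/I = i_sc(V)·(1 − P_o(V)), pA."""
        return self.isc(V) * (1.0 - self.po(V))


# ---------------------------------------------------------------------------
# scalar/array law evaluation
# ---------------------------------------------------------------------------

def _check_finite_V(V):
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ParameterError("membrane voltage must be finite")
    return V


def eval_boltzmann(V, c: BoltzmannComponent):
    """Single Boltzmann sigmoid 1/(1+exp((V_mid − V)/k)); V in mV."""
    V = _check_finite_V(V)
    out = expit((V - c.V_mid) / c.k)
    return out if out.ndim else float(out)


def eval_two_boltzmann(V, tb: TwoBoltzmann):
    """Two-component Boltzmann activation A·B1(V) + (1−A)·B2(V), in [0, 1]."""
    V = _check_finite_V(V)
    out = tb.A * expit((V - tb.c1.V_mid) / tb.c1.k) + (1.0 - tb.A) * expit(
        (V - tb.c2.V_mid) / tb.c2.k
    )
    return out if out.ndim else float(out)


def charge_from_slope(k: float, T: float = CONSTANTS.T) -> float:
    """Gating charge from a Boltzmann slope factor: z = RT/(kF), k in mV.

    The inverse of :func:`slope_from_charge`; a flat curve (large k) carries
    vanishing charge.
    """
    if k <= 0:
        raise ParameterError(f"slope factor k must be positive, got {k}")
    return _thermal_mV(T) / k


def slope_from_charge(z: float, T: float = CONSTANTS.T) -> float:
    """Boltzmann slope factor (mV) for an equivalent charge z: k = RT/(zF)."""
    if z <= 0:
        raise ParameterError(f"equivalent charge z must be positive, got {z}")
    return _thermal_mV(T) / z


def relaxation(V, r: RateLaw, T: float = CONSTANTS.T):
    """Two-state relaxation at V: returns (α, β, τ, po_eq).

    α = a0·exp(za·FV/RT) ms⁻¹, β = b0·exp(−zb·FV/RT) ms⁻¹,
    τ = 1/(α+β) ms, po_eq = α/(α+β).  When za = zb the equilibrium curve is
    a single Boltzmann with total charge za+zb.
    """
    V = _check_finite_V(V)
    vt = _thermal_mV(T)
    alpha = r.a0 * np.exp(r.za * V / vt)
    beta = r.b0 * np.exp(-r.zb * V / vt)
    tau = 1.0 / (alpha + beta)
    po_eq = alpha / (alpha + beta)
    if alpha.ndim == 0:
        return float(alpha), float(beta), float(tau), float(po_eq)
    return alpha, beta, tau, po_eq


def open_pore_current(V, p: PermeationLaw):
    """Single open-channel current i_sc(V) = γ(V)·V/1000 in pA (V in mV, γ in pS)."""
    V = _check_finite_V(V)
    gamma = p.g_plus + (p.g_minus - p.g_plus) * expit(-V / p.V_s)
    out = gamma * V / 1000.0
    return out if out.ndim else float(out)
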