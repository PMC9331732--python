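"""Closed-form gating laws for Kv1.x-style delayed-rectifier channels.

A channel species is described by

* a Boltzmann steady-state activation curve ``m_inf(V) = 1 / (1 + exp(-(V - V_half)/k))``,
* voltage-dependent first-order activation/deactivation time constants that
  follow the exponential law ``tau(V) = tau_Vhalf * exp((V - V_half)/k_tau)``,
* bi-exponential slow (C-type) inactivation described by two parallel
  first-order gates with time constants ``tau_fast``/``tau_slow`` and a fast
  fraction ``frac_fast``, both recovering at hyperpolarized potentials with
  a common ``tau_recovery``,
* an ohmic conductance ``g_max`` and a potassium reversal potential ``E_rev``.

The total open probability is ``O(V, t) = m * (frac_fast*h_f + (1-frac_fast)*h_s)``
with a single (power-1) activation gate, so the conductance-activation curve
equals the Boltzmann exactly and tail-current analysis is unbiased.

These laws are shared verbatim by the simulator (:mod:`kvclamp.simulate`)
and, implicitly, by the fitters in :mod:`kvclamp.analysis` which estimate
their parameters back from current traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

import numpy as np
from scipy import constants
from scipy.special import expit

__all__ = [
    "BoltzmannParams",
    "TauLaw",
    "InactivationParams",
    "ChannelSpecies",
    "MixtureModel",
    "AssemblyRule",
    "steady_state_open",
    "tau_of_V",
    "reversal_potential",
    "mix_coexpression",
    "dominant_negative_amplitude",
    "inactivation_steady_state",
    "inactivation_tau",
    "TAU_CROSSOVER_MV",
    "H_DEPOLARIZED_MV",
    "H_HYPERPOLARIZED_MV",
]

# Voltage below which the deactivation tau-law governs the activation gate.
TAU_CROSSOVER_MV = -40.0
# Inactivation gates use (tau_fast, tau_slow) at/above this potential ...
H_DEPOLARIZED_MV = 0.0
# ... and relax with tau_recovery at/below this one; log-linear in between.
H_HYPERPOLARIZED_MV = -60.0


@dataclass(frozen=True)
class BoltzmannParams:
    """Midpoint ``V_half`` (mV) and slope factor ``k`` (mV) of a Boltzmann curve."""

    V_half: float
    k: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.V_half):
            raise ValueError("V_half must be finite")
        if self.k == 0 or not math.isfinite(self.k):
            raise ValueError("slope factor k must be finite and non-zero")


@dataclass(frozen=True)
class TauLaw:
    """Exponential voltage dependence of a relaxation time constant.

    ``tau(V) = tau_at_Vhalf * exp((V - V_half) / k_tau)`` with ``tau_at_Vhalf``
    in ms, referenced to the activation midpoint ``V_half`` (mV).  ``k_tau`` is
    signed: negative slopes make tau shrink with depolarization (typical for
    activation), positive slopes make it grow (typical for deactivation).
    """

    tau_at_Vhalf: float
    k_tau: float
    V_half: float

    def __post_init__(self) -> None:
        if not (self.tau_at_Vhalf > 0):
            raise ValueError("tau_at_Vhalf must be positive")
        if self.k_tau == 0 or not math.isfinite(self.k_tau):
            raise ValueError("k_tau must be finite and non-zero")
        if not math.isfinite(self.V_half):
            raise ValueError("V_half must be finite")


@dataclass(frozen=True)
class InactivationParams:
    """Bi-exponential C-type inactivation and single-exponential recovery (all seconds)."""

    tau_fast: float
    tau_slow: float
    frac_fast: float
    tau_recovery: float

    def __post_init__(self) -> None:
        if not (0 < self.tau_fast < self.tau_slow):
            raise ValueError("need 0 < tau_fast < tau_slow")
        if not (0 <= self.frac_fast <= 1):
            raise ValueError("frac_fast must lie in [0, 1]")
        if not (self.tau_recovery > 0):
            raise ValueError("tau_recovery must be positive")


@dataclass(frozen=True)
class ChannelSpecies:
    """Full generative parameter set for one homomeric channel population."""

    name: str
    activation: BoltzmannParams
    act_tau: TauLaw
    deact_tau: TauLaw
    inact: InactivationParams
    g_max: float  # conductance scale, display-units / mV
    E_rev: float  # reversal potential, mV

    def __post_init__(self) -> None:
        if not (self.g_max >= 0):
            raise ValueError("g_max must be non-negative")
        if not math.isfinite(self.E_rev):
            raise ValueError("E_rev must be finite")

    # -- gate laws ---------------------------------------------------------

    def m_inf(self, V):
        return steady_state_open(V, self.activation)

    def tau_m(self, V):
        """Activation-gate time constant (ms); activation law above the
        crossover potential, deactivation law below it."""
        V = np.asarray(V, dtype=float)
        act = tau_of_V(V, self.act_tau)
        deact = tau_of_V(V, self.deact_tau)
        return np.where(V >= TAU_CROSSOVER_MV, act, deact)

    def with_g_max(self, g_max: float) -> "ChannelSpecies":
        return replace(self, g_max=g_max)


class AssemblyRule(str, Enum):
    """How WT and mutant subunits combine into tetramers."""

    INDEPENDENT_BINOMIAL = "independent_binomial"
    SINGLE_SPECIES = "single_species"


@dataclass(frozen=True)
class MixtureModel:
    """Weighted mixture of channel species in one cell membrane."""

    components: tuple  # of (ChannelSpecies, weight)
    assembly_rule: AssemblyRule = AssemblyRule.SINGLE_SPECIES

    def __post_init__(self) -> None:
        weights = np.array([w for _, w in self.components], dtype=float)
        if np.any(weights < 0):
            raise ValueError("mixture weights must be non-negative")
        if abs(weights.sum() - 1.0) > 1e-12:
            raise ValueError("mixture weights must sum to 1")


def steady_state_open(V, p: BoltzmannParams):
    """Boltzmann open fraction ``1 / (1 + exp(-(V - V_half)/k))``.

    Strictly increasing in V for k > 0 and exactly 0.5 at ``V_half``.
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("membrane potential must be finite")
    out = expit((V - p.V_half) / p.k)
    return float(out) if out.ndim == 0 else out


def tau_of_V(V, law: TauLaw):
    """Evaluate ``tau(V) = tau_at_Vhalf * exp((V - V_half)/k_tau)`` in ms."""
    V = np.asarray(V, dtype=float)
    out = law.tau_at_Vhalf * np.exp((V - law.V_half) / law.k_tau)
    return float(out) if out.ndim == 0 else out


def reversal_potential(K_out: float, K_in: float, T: float = 293.15) -> float:
    """Nernst potassium reversal potential in mV.

    Parameters are the extracellular and intracellular K+ concentrations (any
    common unit, typically mM) and the absolute temperature in kelvin.
    """
    if K_out <= 0 or K_in <= 0:
        raise ValueError("ion concentrations must be positive")
    if T <= 0:
        raise ValueError("temperature must be positive")
    return 1e3 * constants.R * T / constants.physical_constants["Faraday constant"][0] * math.log(K_out / K_in)


def inactivation_steady_state(V, activation: BoltzmannParams):
    """Steady-state availability of the inactivation gates.

    C-type inactivation proceeds from the open state, so availability is
    coupled to activation: ``h_inf(V) = 1 - m_inf(V)``.  Channels that stay
    closed do not inactivate (availability ~1 at hyperpolarized potentials)
    while sustained depolarization drives availability toward zero -- the
    two regimes the experiments actually constrain (full decay at +40 mV,
    full recovery at -80 mV).
    """
    return 1.0 - steady_state_open(V, activation)


def inactivation_tau(V, tau_depolarized_s: float, tau_recovery_s: float):
    """Time constant (s) of one inactivation gate at potential V.

    ``tau_depolarized_s`` applies for V >= 0 mV, ``tau_recovery_s`` for
    V <= -60 mV, with log-linear interpolation in between.
    """
    V = np.asarray(V, dtype=float)
    frac = np.clip((V - H_HYPERPOLARIZED_MV) / (H_DEPOLARIZED_MV - H_HYPERPOLARIZED_MV), 0.0, 1.0)
    out = np.exp((1 - frac) * np.log(tau_recovery_s) + frac * np.log(tau_depolarized_s))
    return float(out) if out.ndim == 0 else out


def mix_coexpression(
    wt: ChannelSpecies,
    mut: ChannelSpecies,
    cDNA_ratio: float = 0.5,
    rule: AssemblyRule = AssemblyRule.INDEPENDENT_BINOMIAL,
    heteromer: Optional[ChannelSpecies] = None,
) -> MixtureModel:
    """Build the channel mixture produced by co-transfecting WT and mutant cDNA.

    ``cDNA_ratio`` is the WT fraction of total cDNA (0.5 for a 1:1
    co-transfection).  Under ``INDEPENDENT_BINOMIAL`` subunits assemble
    independently, so the tetramer composition is Binomial(4, cDNA_ratio);
    with the dominant-negative rule any tetramer carrying at least one mutant
    subunit gates like the mutant, so the mixture collapses to
    ``(wt, cDNA_ratio**4), (mut, 1 - cDNA_ratio**4)``.  Under
    ``SINGLE_SPECIES`` the heteromeric population is described by one
    externally supplied species (e.g. parameters measured on co-expressed
    channels).
    """
    if not (0 < cDNA_ratio <= 1):
        raise ValueError("cDNA_ratio must lie in (0, 1]")
    if rule == AssemblyRule.SINGLE_SPECIES:
        if heteromer is None:
            raise ValueError("single_species rule requires an explicit heteromer species")
        return MixtureModel(((heteromer, 1.0),), rule)
    if rule != AssemblyRule.INDEPENDENT_BINOMIAL:
        raise ValueError(f"unknown assembly rule {rule!r}")
    w_wt = cDNA_ratio**4
    if cDNA_ratio == 1.0:
        return MixtureModel(((wt, 1.0),), rule)
    return MixtureModel(((wt, w_wt), (mut, 1.0 - w_wt)), rule)


def dominant_negative_amplitude(a_wt: float, a_mut: float, wt_fraction: float = 0.5) -> float:
    """Predicted co-expression current amplitude under dominant-negative
    binomial assembly, given the two homomeric amplitudes measured at the
    same potential."""
    if not (0 < wt_fraction < 1):
        raise ValueError("wt_fraction must lie in (0, 1)")
    w_wt = wt_fraction**4
    return w_wt * a_wt + (1.0 - w_wt) * a_mut
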