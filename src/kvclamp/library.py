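"""Reference Kv1.1 channel definitions and conductance calibration.

The packaged JSON carries the generative parameter sets of the three channel
populations studied experimentally: homomeric wild-type, homomeric P403A,
and the 1:1 co-expressed heteromer treated as a single species.  Loading
fills in the two derived quantities:

* ``E_rev`` from the Nernst equation for the recording solutions
  (2.8 mM K+ bath / 132 mM K+ pipette, 293.15 K), about -97 mV;
* ``g_max`` calibrated so the measured steady IV current at +20 mV equals
  the species' reference amplitude in display units (2.1 WT, 0.4 P403A,
  0.55 heteromer) -- the published current amplitudes carry no absolute
  unit, so the conductance scale is anchored to them.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

import numpy as np

from .analysis import measure_iv
from .gating import (
    AssemblyRule,
    BoltzmannParams,
    ChannelSpecies,
    InactivationParams,
    MixtureModel,
    TauLaw,
    mix_coexpression,
    reversal_potential,
)
from .protocols import Protocol, Sweep, VoltageSegment, build_iv_protocol
from .simulate import simulate_sweep

__all__ = [
    "load_species_definitions",
    "reference_species",
    "reference_mixture",
    "calibrate_g_max",
    "WT",
    "MUT",
    "HET",
]

WT = "Kv1.1-WT"
MUT = "P403A"
HET = "Kv1.1-WT+P403A"

CALIBRATION_STEP_MV = 20.0


def load_species_definitions() -> dict:
    """Raw packaged JSON (species parameters + recording solutions)."""
    with resources.files("kvclamp.data").joinpath("kv11_species.json").open() as fh:
        return json.load(fh)


def _species_from_dict(d: dict, E_rev: float, g_max: float = 1.0) -> ChannelSpecies:
    vh = d["activation"]["V_half"]
    return ChannelSpecies(
        name=d["name"],
        activation=BoltzmannParams(vh, d["activation"]["k"]),
        act_tau=TauLaw(d["act_tau"]["tau_at_Vhalf"], d["act_tau"]["k_tau"], vh),
        deact_tau=TauLaw(d["deact_tau"]["tau_at_Vhalf"], d["deact_tau"]["k_tau"], vh),
        inact=InactivationParams(
            d["inact"]["tau_fast"],
            d["inact"]["tau_slow"],
            d["inact"]["frac_fast"],
            d["inact"]["tau_recovery"],
        ),
        g_max=d["g_max"] if d.get("g_max") is not None else g_max,
        E_rev=E_rev,
    )


def calibrate_g_max(
    species: ChannelSpecies, target_amplitude: float, step_mV: float = CALIBRATION_STEP_MV
) -> ChannelSpecies:
    """Rescale ``g_max`` so the steady IV measurement at ``step_mV`` equals
    ``target_amplitude``.

    The calibration simulates the actual IV sweep noise-free and applies the
    same baseline-subtracted last-10%-of-step measure used by the analysis,
    so the anchored amplitude is exactly what the pipeline reports.  The
    current is linear in g_max, so one simulation suffices.
    """
    protocol = build_iv_protocol()
    sweep = next(
        sw for sw in protocol.sweeps if sw.segments[1].level == step_mV
    )
    trace = simulate_sweep(species, sweep, noise_sd=0.0)
    measured = measure_iv([trace], protocol)["current"].iloc[0]
    if measured == 0:
        raise ValueError("calibration sweep produced zero current")
    return species.with_g_max(species.g_max * target_amplitude / measured)


@lru_cache(maxsize=None)
def reference_species(calibrate: bool = True) -> dict[str, ChannelSpecies]:
    """The three reference channel populations, keyed by name."""
    defs = load_species_definitions()
    sol = defs["solutions"]
    E_rev = reversal_potential(sol["K_out_mM"], sol["K_in_mM"], sol["temperature_K"])
    out = {}
    for d in defs["species"]:
        sp = _species_from_dict(d, E_rev)
        if calibrate and d.get("amplitude_at_plus20") is not None:
            sp = calibrate_g_max(sp, d["amplitude_at_plus20"])
        out[sp.name] = sp
    return out


def reference_tail_potentials() -> dict[str, float]:
    """Conventional tail potential per species (-50 mV WT, -30 mV mutant/heteromer)."""
    return {d["name"]: d["tail_V"] for d in load_species_definitions()["species"]}


def reference_mixture(rule: AssemblyRule = AssemblyRule.INDEPENDENT_BINOMIAL) -> MixtureModel:
    """The 1:1 WT/P403A co-expression mixture.

    Under binomial assembly with the dominant-negative rule the mixture is
    6.25% WT-like and 93.75% mutant-like channels; under the single-species
    rule it is the measured heteromeric population."""
    sp = reference_species()
    return mix_coexpression(sp[WT], sp[MUT], 0.5, rule, heteromer=sp[HET])
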