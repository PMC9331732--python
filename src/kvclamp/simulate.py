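"""Synthetic-data engine.

Two generators live here:

* whole-cell potassium-current traces for cells expressing a
  :class:`~kvclamp.gating.ChannelSpecies` or
  :class:`~kvclamp.gating.MixtureModel` under the protocols of
  :mod:`kvclamp.protocols`, and cohorts of such cells with inter-cell
  parameter jitter and additive recording noise;
* synthetic four-fold helical-bundle trajectories with an imposed kink at
  the PVP position, consumed by :mod:`kvclamp.geometry`.

Commands are piecewise-constant in voltage, so every first-order gate
relaxes in closed form within a segment:

    x(t) = x_inf(V) - (x_inf(V) - x_0) * exp(-t / tau_x(V))

and the membrane current is ``I(t) = sum_c w_c * g_max_c * O_c(t) * (V - E_rev_c)``.
Gates start each sweep at their steady state for the holding potential
(long inter-sweep rests are assumed).  Gaussian recording noise is added
after signal synthesis; at ``noise_sd = 0`` traces are deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from .gating import (
    AssemblyRule,
    BoltzmannParams,
    ChannelSpecies,
    InactivationParams,
    MixtureModel,
    TauLaw,
    inactivation_steady_state,
    inactivation_tau,
)
from .geometry import HELIX_RADIUS_A, HELIX_RISE_A, HELIX_TWIST_DEG, Trajectory
from .protocols import Protocol, Sweep

__all__ = [
    "Trace",
    "CohortSpec",
    "simulate_sweep",
    "simulate_protocol",
    "simulate_cell",
    "simulate_cohort",
    "jitter_species",
    "make_helix_bundle",
]

Model = Union[ChannelSpecies, MixtureModel]


@dataclass
class Trace:
    """One simulated (or loaded) current sweep."""

    time_ms: np.ndarray
    current: np.ndarray  # display units
    command_mV: np.ndarray
    sweep_label: str = ""
    cell_id: str = "cell000"

    def __post_init__(self) -> None:
        if not (len(self.time_ms) == len(self.current) == len(self.command_mV)):
            raise ValueError("time, current and command vectors must share a length")
        if np.any(np.diff(self.time_ms) <= 0):
            raise ValueError("time must be strictly increasing")


def _components(model: Model) -> list[tuple[ChannelSpecies, float]]:
    if isinstance(model, ChannelSpecies):
        return [(model, 1.0)]
    if isinstance(model, MixtureModel):
        return list(model.components)
    raise TypeError(f"unsupported model type {type(model).__name__}")


def _gate_signal(species: ChannelSpecies, sweep: Sweep) -> np.ndarray:
    """Noise-free current of one species under one sweep (closed form)."""
    bounds = sweep.segment_sample_bounds()
    n = bounds[-1][1]
    fs_ms = sweep.sampling_rate / 1e3  # samples per ms
    current = np.empty(n)
    hold = sweep.holding
    m = species.m_inf(hold)
    h_f = inactivation_steady_state(hold, species.activation)
    h_s = h_f
    ff = species.inact.frac_fast
    for seg, (i0, i1) in zip(sweep.segments, bounds):
        V = seg.level
        t_ms = (np.arange(i1 - i0)) / fs_ms
        m_inf = species.m_inf(V)
        tau_m = float(species.tau_m(V))  # ms
        h_inf = inactivation_steady_state(V, species.activation)
        tau_hf = 1e3 * inactivation_tau(V, species.inact.tau_fast, species.inact.tau_recovery)
        tau_hs = 1e3 * inactivation_tau(V, species.inact.tau_slow, species.inact.tau_recovery)
        em = np.exp(-t_ms / tau_m)
        ef = np.exp(-t_ms / tau_hf)
        es = np.exp(-t_ms / tau_hs)
        m_t = m_inf - (m_inf - m) * em
        hf_t = h_inf - (h_inf - h_f) * ef
        hs_t = h_inf - (h_inf - h_s) * es
        O = m_t * (ff * hf_t + (1 - ff) * hs_t)
        current[i0:i1] = species.g_max * O * (V - species.E_rev)
        # carry exact end-of-segment gate values into the next segment
        dur = seg.duration
        m = m_inf - (m_inf - m) * math.exp(-dur / tau_m)
        h_f = h_inf - (h_inf - h_f) * math.exp(-dur / tau_hf)
        h_s = h_inf - (h_inf - h_s) * math.exp(-dur / tau_hs)
    return current


def simulate_sweep(
    model: Model,
    sweep: Sweep,
    noise_sd: float = 0.0,
    rng: Optional[Union[int, np.random.Generator]] = None,
    cell_id: str = "cell000",
    g_leak: float = 0.0,
    noise_filter_hz: Optional[float] = None,
) -> Trace:
    """Simulate one sweep for one cell.

    ``noise_sd`` is the SD of additive Gaussian recording noise in display
    units; ``noise_filter_hz`` optionally low-pass filters the noise with a
    4-pole Bessel filter (emulating the acquisition filter) and is off by
    default so that noise-free traces stay exact.  ``g_leak`` adds an ohmic
    leak with a 0 mV reversal.
    """
    bounds = sweep.segment_sample_bounds()
    n = bounds[-1][1]
    current = np.zeros(n)
    for species, weight in _components(model):
        current += weight * _gate_signal(species, sweep)
    command = np.empty(n)
    for seg, (i0, i1) in zip(sweep.segments, bounds):
        command[i0:i1] = seg.level
    if g_leak:
        current += g_leak * command
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        noise = gen.normal(0.0, noise_sd, n)
        if noise_filter_hz:
            from scipy.signal import bessel, lfilter

            b, a = bessel(4, noise_filter_hz / (sweep.sampling_rate / 2))
            noise = lfilter(b, a, noise)
        current = current + noise
    time_ms = np.arange(n) * (1e3 / sweep.sampling_rate)
    return Trace(time_ms, current, command, sweep.label, cell_id)


def simulate_protocol(
    model: Model,
    protocol: Protocol,
    noise_sd: float = 0.0,
    rng: Optional[Union[int, np.random.Generator]] = None,
    cell_id: str = "cell000",
    **kwargs,
) -> list[Trace]:
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    return [
        simulate_sweep(model, sw, noise_sd=noise_sd, rng=gen, cell_id=cell_id, **kwargs)
        for sw in protocol.sweeps
    ]


def simulate_cell(
    model: Model,
    protocols: Sequence[Protocol],
    noise_sd: float = 0.0,
    rng: Optional[Union[int, np.random.Generator]] = None,
    cell_id: str = "cell000",
) -> dict[str, list[Trace]]:
    """Simulate a full protocol battery for one cell; keyed by protocol kind."""
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    return {
        p.kind: simulate_protocol(model, p, noise_sd=noise_sd, rng=gen, cell_id=cell_id)
        for p in protocols
    }


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of a cohort of recorded cells.

    ``jitter_cv`` is the coefficient of variation of the multiplicative
    log-normal inter-cell jitter applied to positive-definite parameters;
    the activation midpoint is jittered additively (normal,
    sd = jitter_cv * 10 mV) because it is not positive-definite.
    """

    n_cells: int
    base: Model
    jitter_cv: float = 0.1
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.jitter_cv < 0 or self.noise_sd < 0:
            raise ValueError("jitter_cv and noise_sd must be non-negative")


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    if cv == 0:
        return 1.0
    sigma = math.sqrt(math.log(1 + cv**2))
    return float(rng.lognormal(mean=-sigma**2 / 2, sigma=sigma))


def jitter_species(base: ChannelSpecies, cv: float, rng: np.random.Generator) -> ChannelSpecies:
    """Draw one cell's parameters around a base species.

    Multiplicative mean-one log-normal jitter for positive parameters keeps
    every invariant valid at any CV; V_half gets additive normal jitter.
    """
    dV = rng.normal(0.0, cv * 10.0)
    act = BoltzmannParams(base.activation.V_half + dV, base.activation.k * _lognormal_factor(rng, cv))
    act_tau = TauLaw(
        base.act_tau.tau_at_Vhalf * _lognormal_factor(rng, cv),
        base.act_tau.k_tau * _lognormal_factor(rng, cv),
        act.V_half,
    )
    deact_tau = TauLaw(
        base.deact_tau.tau_at_Vhalf * _lognormal_factor(rng, cv),
        base.deact_tau.k_tau * _lognormal_factor(rng, cv),
        act.V_half,
    )
    tf = base.inact.tau_fast * _lognormal_factor(rng, cv)
    ts = base.inact.tau_slow * _lognormal_factor(rng, cv)
    if tf >= ts:  # keep fast < slow under extreme draws
        tf, ts = min(tf, ts) * 0.999, max(tf, ts)
    ff = min(0.99, max(0.01, base.inact.frac_fast * _lognormal_factor(rng, cv)))
    inact = InactivationParams(tf, ts, ff, base.inact.tau_recovery * _lognormal_factor(rng, cv))
    return replace(
        base,
        activation=act,
        act_tau=act_tau,
        deact_tau=deact_tau,
        inact=inact,
        g_max=base.g_max * _lognormal_factor(rng, cv),
    )


def _jitter_model(base: Model, cv: float, rng: np.random.Generator) -> Model:
    if isinstance(base, ChannelSpecies):
        return jitter_species(base, cv, rng)
    comps = tuple((jitter_species(sp, cv, rng), w) for sp, w in base.components)
    return MixtureModel(comps, base.assembly_rule)


def simulate_cohort(
    spec: CohortSpec, protocols: Sequence[Protocol]
) -> dict[str, dict[str, list[Trace]]]:
    """Simulate every cell of a cohort; reproducible under a fixed seed.

    Returns ``{cell_id: {protocol_kind: [Trace, ...]}}``.
    """
    rng = np.random.default_rng(spec.seed)
    out: dict[str, dict[str, list[Trace]]] = {}
    for i in range(spec.n_cells):
        cell_id = f"cell{i:03d}"
        model = _jitter_model(spec.base, spec.jitter_cv, rng)
        out[cell_id] = simulate_cell(
            model, protocols, noise_sd=spec.noise_sd, rng=rng, cell_id=cell_id
        )
    return out


# ---------------------------------------------------------------------------
# synthetic helical bundles


def _rotation(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle_rad) * K + (1 - math.cos(angle_rad)) * (K @ K)


def _kinked_helix(
    res_ids: np.ndarray, kink_residue: int, kink_deg: float
) -> np.ndarray:
    """C-alpha coordinates of an ideal alpha-helix running down the z axis,
    bent by ``kink_deg`` at ``kink_residue``.

    The segment N-terminal to the kink (the extracellular top of S6, which
    carries G385) pivots radially about the axis point at the kink while the
    C-terminal segment stays put, so increasing the kink of one subunit
    displaces its S6 top and breaks the bundle's symmetry at G385 -- the
    asymmetry signature observed in mutant simulations."""
    n = len(res_ids)
    idx = np.arange(n)
    phase = np.radians(HELIX_TWIST_DEG) * idx
    coords = np.column_stack(
        [
            HELIX_RADIUS_A * np.cos(phase),
            HELIX_RADIUS_A * np.sin(phase),
            -HELIX_RISE_A * idx,  # N-term (extracellular top) at z = 0, running down
        ]
    )
    if kink_deg:
        pivot_i = int(np.where(res_ids == kink_residue)[0][0])
        pivot = np.array([0.0, 0.0, coords[pivot_i, 2]])  # on the helix axis
        R = _rotation([0.0, 1.0, 0.0], math.radians(kink_deg))
        above = res_ids < kink_residue
        coords[above] = (coords[above] - pivot) @ R.T + pivot
    return coords


def make_helix_bundle(
    n_subunits: int = 4,
    kink_deg: float = 25.0,
    kink_residue: int = 403,
    asym_subunit: Optional[int] = None,
    asym_extra_deg: float = 0.0,
    n_frames: int = 1,
    coord_noise_A: float = 0.0,
    frame_dt_ns: float = 0.1,
    seed: Optional[int] = None,
    first_residue: int = 378,
    last_residue: int = 420,
    bundle_radius_A: float = 15.0,
) -> Trajectory:
    """Generate a synthetic C_n-symmetric bundle of kinked helices.

    Emulates the S6 bundle of a Kv channel pore: ideal alpha-helices
    (1.5 A rise, 100 deg twist per residue) arranged with exact n-fold
    symmetry about z, each bent by ``kink_deg`` at ``kink_residue`` (the
    first PVP proline by default).  ``asym_subunit`` (0-based) is bent by
    ``kink_deg + asym_extra_deg`` instead, breaking the symmetry the way a
    destabilized mutant subunit would.  Per-frame Gaussian coordinate noise
    of SD ``coord_noise_A`` is added; frames are stamped every
    ``frame_dt_ns``.
    """
    if n_subunits < 3:
        raise ValueError("need at least 3 subunits")
    if not (0 <= kink_deg < 90):
        raise ValueError("kink_deg must lie in [0, 90)")
    res_ids = np.arange(first_residue, last_residue + 1)
    if kink_residue not in res_ids or kink_residue in (first_residue, last_residue):
        raise ValueError("kink_residue must lie strictly inside the modeled range")
    if asym_subunit is not None and not (0 <= asym_subunit < n_subunits):
        raise ValueError("asym_subunit out of range")
    n_res = len(res_ids)
    chains = [chr(ord("A") + i) for i in range(n_subunits)]
    coords = np.empty((n_subunits, n_res, 3))
    offset = np.array([bundle_radius_A, 0.0, 0.0])
    for i in range(n_subunits):
        angle = kink_deg + (asym_extra_deg if i == asym_subunit else 0.0)
        helix = _kinked_helix(res_ids, kink_residue, angle) + offset
        Rz = _rotation([0.0, 0.0, 1.0], 2 * math.pi * i / n_subunits)
        coords[i] = helix @ Rz.T
    flat = coords.reshape(-1, 3)

    n_atoms = n_subunits * n_res
    res_names = np.full(n_res, "ALA", dtype="U5")
    res_names[res_ids == 385] = "GLY"
    res_names[res_ids == kink_residue] = "PRO"
    res_names[res_ids == kink_residue + 2] = "PRO"
    res_names[res_ids == kink_residue + 1] = "VAL"

    rng = np.random.default_rng(seed)
    frames = np.repeat(flat[None, :, :], n_frames, axis=0)
    if coord_noise_A > 0:
        frames = frames + rng.normal(0.0, coord_noise_A, frames.shape)
    return Trajectory(
        chain_id=np.repeat(chains, n_res),
        res_id=np.tile(res_ids, n_subunits),
        atom_name=np.full(n_atoms, "CA"),
        coords=frames,
        times_ns=np.arange(n_frames) * frame_dt_ns,
        res_name=np.tile(res_names, n_subunits),
    )
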