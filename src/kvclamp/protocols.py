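"""Machine-readable voltage-clamp protocols and builders for the five
standard Kv1.1 characterization protocols:

``iv``            200 ms steps from a -80 mV holding potential to -80 ... +60 mV
                  (10 mV intervals).
``tail``          the same prepulse family, each prepulse followed by a 150 ms
                  tail step at -50 mV (WT convention) or -30 mV (mutant
                  convention).
``deactivation``  200 ms conditioning pulse at +20 mV followed by 200 ms
                  post-steps from -80 ... +20 mV.
``inactivation``  a single 90 s pulse at +40 mV.
``recovery``      double pulse: 20 s conditioning at +20 mV, variable
                  interpulse interval at holding, 100 ms probe at +20 mV.

Every sweep opens with a 10 ms baseline at the holding potential (so the
analysis always has a baseline window) and closes at holding.  Protocols
serialize losslessly to/from JSON descriptors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "VoltageSegment",
    "Sweep",
    "Protocol",
    "build_iv_protocol",
    "build_tail_protocol",
    "build_deactivation_protocol",
    "build_inactivation_protocol",
    "build_recovery_protocol",
    "build_protocol",
    "PROTOCOL_BUILDERS",
    "DEFAULT_RECOVERY_INTERVALS_S",
]

HOLDING_MV = -80.0
BASELINE_MS = 10.0
CLOSING_MS = 50.0
#: interpulse grid 0.1, 1.1, ..., 17.1 s (18 sweeps spanning the stated range)
DEFAULT_RECOVERY_INTERVALS_S = tuple(round(0.1 + i, 1) for i in range(18))


@dataclass(frozen=True)
class VoltageSegment:
    """A constant command-voltage epoch: level in mV, duration in ms."""

    level: float
    duration: float

    def __post_init__(self) -> None:
        if not (self.duration > 0):
            raise ValueError("segment duration must be positive")


@dataclass(frozen=True)
class Sweep:
    segments: tuple  # of VoltageSegment
    holding: float
    sampling_rate: float  # Hz
    label: str = ""

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("sweep needs at least one segment")
        if not (self.sampling_rate > 0):
            raise ValueError("sampling_rate must be positive")
        if self.segments[0].level != self.holding or self.segments[-1].level != self.holding:
            raise ValueError("sweep must start and end at the holding potential")

    @property
    def duration_ms(self) -> float:
        return sum(s.duration for s in self.segments)

    def segment_sample_bounds(self) -> list[tuple[int, int]]:
        """Half-open sample index ranges [start, stop) for each segment.

        Sample n sits at t = n / sampling_rate; the first sample of a segment
        falls exactly on the segment boundary (local t = 0).
        """
        dt_ms = 1e3 / self.sampling_rate
        bounds = []
        edge = 0.0
        start = 0
        for seg in self.segments:
            edge += seg.duration
            stop = int(round(edge / dt_ms))
            bounds.append((start, stop))
            start = stop
        return bounds

    @property
    def n_samples(self) -> int:
        return self.segment_sample_bounds()[-1][1]


@dataclass(frozen=True)
class Protocol:
    sweeps: tuple  # of Sweep
    kind: str

    def __post_init__(self) -> None:
        if not self.sweeps:
            raise ValueError("protocol needs at least one sweep")
        rates = {s.sampling_rate for s in self.sweeps}
        if len(rates) != 1:
            raise ValueError("all sweeps of a protocol must share one sampling rate")

    @property
    def sampling_rate(self) -> float:
        return self.sweeps[0].sampling_rate

    # -- JSON round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "sweeps": [
                {
                    "label": s.label,
                    "holding": s.holding,
                    "sampling_rate": s.sampling_rate,
                    "segments": [{"level": g.level, "duration": g.duration} for g in s.segments],
                }
                for s in self.sweeps
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Protocol":
        sweeps = tuple(
            Sweep(
                segments=tuple(VoltageSegment(g["level"], g["duration"]) for g in s["segments"]),
                holding=s["holding"],
                sampling_rate=s["sampling_rate"],
                label=s.get("label", ""),
            )
            for s in d["sweeps"]
        )
        return cls(sweeps=sweeps, kind=d["kind"])

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path) -> "Protocol":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _sweep(levels_durations, sampling_rate, label, holding=HOLDING_MV) -> Sweep:
    segs = [VoltageSegment(holding, BASELINE_MS)]
    segs += [VoltageSegment(level, dur) for level, dur in levels_durations]
    segs += [VoltageSegment(holding, CLOSING_MS)]
    return Sweep(tuple(segs), holding, sampling_rate, label)


def step_family(start=-80.0, stop=60.0, step=10.0) -> list[float]:
    n = int(round((stop - start) / step)) + 1
    return [start + i * step for i in range(n)]


def build_iv_protocol(sampling_rate: float = 50_000.0) -> Protocol:
    """Current-voltage protocol: 200 ms steps, -80 ... +60 mV by 10 mV."""
    sweeps = tuple(
        _sweep([(V, 200.0)], sampling_rate, f"iv_{V:+.0f}mV") for V in step_family()
    )
    return Protocol(sweeps, "iv")


def build_tail_protocol(tail_V: float = -50.0, sampling_rate: float = 50_000.0) -> Protocol:
    """Tail-current protocol: the IV prepulse family, each prepulse followed
    by a 150 ms tail step (-50 mV WT convention, -30 mV mutant convention)."""
    if tail_V not in (-50.0, -30.0):
        warnings.warn(
            f"non-standard tail potential {tail_V} mV (conventional values are -50 and -30)",
            stacklevel=2,
        )
    sweeps = tuple(
        _sweep([(V, 200.0), (tail_V, 150.0)], sampling_rate, f"tail_{V:+.0f}mV")
        for V in step_family()
    )
    return Protocol(sweeps, "tail")


def build_deactivation_protocol(sampling_rate: float = 50_000.0) -> Protocol:
    """Deactivation protocol: 200 ms at +20 mV then 200 ms post-steps
    -80 ... +20 mV by 10 mV."""
    sweeps = tuple(
        _sweep([(20.0, 200.0), (V, 200.0)], sampling_rate, f"deact_{V:+.0f}mV")
        for V in step_family(-80.0, 20.0)
    )
    return Protocol(sweeps, "deactivation")


def build_inactivation_protocol(sampling_rate: float = 10_000.0) -> Protocol:
    """C-type inactivation protocol: one 90 s pulse to +40 mV.

    The default sampling rate is reduced to 10 kHz; the decay under study has
    multi-second time constants and a 90 s sweep at the full acquisition rate
    would be needlessly large.
    """
    return Protocol((_sweep([(40.0, 90_000.0)], sampling_rate, "inact_+40mV"),), "inactivation")


def build_recovery_protocol(
    intervals_s: Optional[Sequence[float]] = None, sampling_rate: float = 10_000.0
) -> Protocol:
    """Recovery-from-inactivation double-pulse protocol.

    Each sweep: 20 s conditioning pulse at +20 mV, interpulse interval at the
    holding potential, 100 ms probe pulse at +20 mV.  Default intervals span
    0.1-17.1 s in 1 s increments.
    """
    if intervals_s is None:
        intervals_s = DEFAULT_RECOVERY_INTERVALS_S
    intervals_s = list(intervals_s)
    if not intervals_s:
        raise ValueError("need at least one interpulse interval")
    if any(b <= a for a, b in zip(intervals_s, intervals_s[1:])):
        raise ValueError("interpulse intervals must be strictly increasing")
    if any(i <= 0 for i in intervals_s):
        raise ValueError("interpulse intervals must be positive")
    sweeps = tuple(
        _sweep(
            [(20.0, 20_000.0), (HOLDING_MV, 1e3 * dt), (20.0, 100.0)],
            sampling_rate,
            f"rec_{dt:g}s",
        )
        for dt in intervals_s
    )
    return Protocol(sweeps, "recovery")


PROTOCOL_BUILDERS = {
    "iv": build_iv_protocol,
    "tail": build_tail_protocol,
    "deactivation": build_deactivation_protocol,
    "inactivation": build_inactivation_protocol,
    "recovery": build_recovery_protocol,
}


def build_protocol(name_or_path: str, **kwargs) -> Protocol:
    """Build a named protocol, or load a JSON descriptor if given a path."""
    if name_or_path in PROTOCOL_BUILDERS:
        return PROTOCOL_BUILDERS[name_or_path](**kwargs)
    path = Path(name_or_path)
    if path.exists():
        return Protocol.load(path)
    raise ValueError(
        f"unknown protocol {name_or_path!r}; expected one of {sorted(PROTOCOL_BUILDERS)} or a JSON path"
    )
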