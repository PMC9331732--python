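"""Trajectory geometry of the Kv1.1 pore: S6 kink angles and four-fold
symmetry angles at the top of S6 (G385), with windowed trajectory statistics.

The S6 helix of each subunit is kinked at the PVP motif (P403-V404-P405).
The kink angle is measured as the angle between the helix axes of the S6
above and below the motif; the default axis windows are residues 389-401
(upper) and 405-417 (lower), excluding the motif itself.  The symmetry
angles are the interior angles of the quadrilateral formed by the G385
C-alpha atoms of the four subunits: 90 degrees each for a perfectly
four-fold-symmetric pore, spreading apart when one subunit deviates.

Trajectories are multi-model PDB files (MODEL/ENDMDL records); frame times
in ns are carried in ``REMARK 250 FRAME TIMES (NS)`` records and fall back
to a uniform grid when absent.  File parsing and writing go through biotite;
in-memory frames keep float64 coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Trajectory",
    "Frame",
    "HelixSegment",
    "GeometryError",
    "read_trajectory",
    "write_trajectory",
    "helix_axis",
    "kink_angle",
    "symmetry_angles",
    "trajectory_stats",
    "UPPER_S6_SEGMENT",
    "LOWER_S6_SEGMENT",
    "G385",
]

#: C-alpha position used for the symmetry-angle measurement (top of S6).
G385 = 385

# Ideal alpha-helix geometry (per residue).
HELIX_TWIST_DEG = 100.0
HELIX_RISE_A = 1.5
HELIX_RADIUS_A = 2.3

_REMARK_TAG = "250 FRAME TIMES (NS):"


class GeometryError(ValueError):
    """Raised for malformed trajectories or invalid geometric queries."""


@dataclass(frozen=True)
class HelixSegment:
    """A contiguous residue range of one chain used for axis estimation."""

    chain_id: str
    first: int
    last: int

    def __post_init__(self) -> None:
        if self.last - self.first < 4:
            raise ValueError("helix segment needs at least 5 residues for an axis")


def upper_s6_segment(chain_id: str) -> HelixSegment:
    """S6 window above the PVP motif (residues 389-401)."""
    return HelixSegment(chain_id, 389, 401)


def lower_s6_segment(chain_id: str) -> HelixSegment:
    """S6 window below the PVP motif (residues 405-417)."""
    return HelixSegment(chain_id, 405, 417)


UPPER_S6_SEGMENT = (389, 401)
LOWER_S6_SEGMENT = (405, 417)


@dataclass
class Frame:
    """One trajectory frame: per-atom annotations plus float64 coordinates.

    Coordinates are kept in double precision so that angle operations are
    rigid-motion invariant to microdegrees; the float32/fixed-point rounding
    of structure-file containers applies only at the file boundary.
    """

    chain_id: np.ndarray
    res_id: np.ndarray
    atom_name: np.ndarray
    coord: np.ndarray
    time_ns: float = 0.0
    res_name: Optional[np.ndarray] = None

    def copy(self) -> "Frame":
        return Frame(
            self.chain_id.copy(),
            self.res_id.copy(),
            self.atom_name.copy(),
            self.coord.copy(),
            self.time_ns,
            None if self.res_name is None else self.res_name.copy(),
        )

    def select(self, mask: np.ndarray) -> "Frame":
        return Frame(
            self.chain_id[mask],
            self.res_id[mask],
            self.atom_name[mask],
            self.coord[mask],
            self.time_ns,
            None if self.res_name is None else self.res_name[mask],
        )


@dataclass
class Trajectory:
    """Time-stamped multi-frame coordinate set with shared topology."""

    chain_id: np.ndarray
    res_id: np.ndarray
    atom_name: np.ndarray
    coords: np.ndarray  # (n_frames, n_atoms, 3), Angstrom, float64
    times_ns: np.ndarray
    res_name: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise GeometryError("coords must have shape (n_frames, n_atoms, 3)")
        if len(self.times_ns) != self.coords.shape[0]:
            raise GeometryError("frame-time vector does not match the number of models")
        if len(self.times_ns) > 1 and not np.all(np.diff(self.times_ns) > 0):
            raise GeometryError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> Frame:
        return Frame(
            self.chain_id, self.res_id, self.atom_name, self.coords[i],
            float(self.times_ns[i]), self.res_name,
        )

    @property
    def span_ns(self) -> float:
        return float(self.times_ns[-1] - self.times_ns[0])


# ---------------------------------------------------------------------------
# multi-model PDB I/O


def _to_stack(traj: Trajectory) -> struc.AtomArrayStack:
    n_frames, n_atoms, _ = traj.coords.shape
    stack = struc.AtomArrayStack(n_frames, n_atoms)
    stack.chain_id = np.asarray(traj.chain_id, dtype="U4")
    stack.res_id = np.asarray(traj.res_id)
    stack.atom_name = np.asarray(traj.atom_name, dtype="U6")
    stack.res_name = (
        np.asarray(traj.res_name, dtype="U5")
        if traj.res_name is not None
        else np.full(n_atoms, "ALA", dtype="U5")
    )
    stack.element = np.where(stack.atom_name == "CA", "C", "X")
    stack.hetero = np.zeros(n_atoms, dtype=bool)
    stack.coord = traj.coords
    return stack


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a multi-model PDB with frame times in REMARK 250 records."""
    pdb = PDBFile()
    pdb.set_structure(_to_stack(traj))
    times = " ".join(f"{t:.4f}" for t in traj.times_ns)
    remarks = []
    # PDB lines are 80 columns; chunk the time list across REMARK records
    prefix = f"REMARK {_REMARK_TAG} "
    budget = 79 - len(prefix)
    line = ""
    for tok in times.split():
        cand = tok if not line else line + " " + tok
        if len(cand) > budget:
            remarks.append(prefix + line)
            line = tok
        else:
            line = cand
    if line:
        remarks.append(prefix + line)
    pdb.lines = remarks + pdb.lines
    Path(path).write_text("\n".join(pdb.lines) + "\n")


def read_trajectory(path, frame_dt_ns: float = 0.1) -> Trajectory:
    """Read a multi-model PDB trajectory.

    Frame times are taken from ``REMARK 250 FRAME TIMES (NS)`` records when
    present, else a uniform grid with spacing ``frame_dt_ns`` is assumed.
    """
    path = Path(path)
    if not path.exists():
        raise GeometryError(f"trajectory file not found: {path}")
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    if isinstance(stack, struc.AtomArray):  # single MODEL
        stack = struc.stack([stack])
    tokens: list[str] = []
    for line in pdb.lines:
        if line.startswith(f"REMARK {_REMARK_TAG}"):
            tokens += line[len(f"REMARK {_REMARK_TAG}") :].split()
    if tokens:
        times = np.array([float(t) for t in tokens])
        if len(times) != stack.stack_depth():
            raise GeometryError(
                f"found {len(times)} frame times for {stack.stack_depth()} models"
            )
    else:
        times = np.arange(stack.stack_depth()) * frame_dt_ns
    return Trajectory(
        chain_id=np.asarray(stack.chain_id),
        res_id=np.asarray(stack.res_id),
        atom_name=np.asarray(stack.atom_name),
        coords=np.asarray(stack.coord, dtype=float),
        times_ns=times,
        res_name=np.asarray(stack.res_name),
    )


# ---------------------------------------------------------------------------
# axis / angle primitives


def _segment_ca(frame: Frame, seg: HelixSegment) -> np.ndarray:
    mask = (
        (frame.chain_id == seg.chain_id)
        & (frame.atom_name == "CA")
        & (frame.res_id >= seg.first)
        & (frame.res_id <= seg.last)
    )
    sub = frame.select(mask)
    order = np.argsort(sub.res_id, kind="stable")
    res_ids = sub.res_id[order]
    expected = seg.last - seg.first + 1
    if len(res_ids) != expected or not np.array_equal(
        res_ids, np.arange(seg.first, seg.last + 1)
    ):
        raise GeometryError(
            f"chain {seg.chain_id}: need one C-alpha per residue {seg.first}-{seg.last}, "
            f"found {len(res_ids)}"
        )
    return sub.coord[order].astype(float)


# Smoothing kernel that cancels the helical wheel exactly for a 100 deg/residue
# helix: with half-angle weights a = -cos(50deg)/cos(150deg), the 4-point
# weighted average of consecutive C-alphas lies on the helix axis for any
# phase, so the principal component of the smoothed points is the exact axis.
_KERNEL_EDGE = -math.cos(math.radians(HELIX_TWIST_DEG / 2)) / math.cos(
    math.radians(1.5 * HELIX_TWIST_DEG)
)
_AXIS_KERNEL = np.array([_KERNEL_EDGE, 1.0, 1.0, _KERNEL_EDGE])
_AXIS_KERNEL = _AXIS_KERNEL / _AXIS_KERNEL.sum()


def _smooth_ca(coords: np.ndarray) -> np.ndarray:
    n = len(coords) - len(_AXIS_KERNEL) + 1
    out = np.empty((n, 3))
    for d in range(3):
        out[:, d] = np.convolve(coords[:, d], _AXIS_KERNEL[::-1], mode="valid")
    return out


def helix_axis(frame: Frame, seg: HelixSegment) -> tuple[np.ndarray, np.ndarray]:
    """Helix axis of a C-alpha segment as (unit vector, centroid).

    The C-alpha trace is first smoothed with a one-turn kernel that cancels
    the helical wheel, then the principal component (largest-variance
    direction) of the smoothed points is taken.  The axis is oriented from
    the N-terminal toward the C-terminal end of the segment.
    """
    coords = _segment_ca(frame, seg)
    pts = _smooth_ca(coords)
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    axis = vt[0]
    if np.dot(axis, pts[-1] - pts[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis), centroid


def kink_angle(
    frame: Frame,
    chain_id: str,
    upper: Optional[HelixSegment] = None,
    lower: Optional[HelixSegment] = None,
) -> float:
    """S6 kink angle (degrees): the angle between the helix axes above and
    below the PVP motif of one chain, in [0, 180]."""
    if upper is None:
        upper = upper_s6_segment(chain_id)
    if lower is None:
        lower = lower_s6_segment(chain_id)
    if upper.chain_id != chain_id or lower.chain_id != chain_id:
        raise GeometryError("both segments must belong to the requested chain")
    if not (upper.last < lower.first or lower.last < upper.first):
        raise GeometryError("upper and lower segments must be disjoint")
    ax_u, _ = helix_axis(frame, upper)
    ax_l, _ = helix_axis(frame, lower)
    cosang = float(np.clip(np.dot(ax_u, ax_l), -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def chain_kink_angles(frame: Frame) -> np.ndarray:
    """Kink angle per chain (sorted chain order), default S6 windows."""
    chains = sorted(set(frame.chain_id))
    return np.array([kink_angle(frame, c) for c in chains])


def symmetry_angles(frame: Frame, residue: int = G385) -> np.ndarray:
    """Interior angle (degrees) at each subunit's reference C-alpha.

    For subunit i, the angle between the vectors from its residue-``residue``
    C-alpha to the equivalent atoms of its two pore-adjacent neighbors.
    Neighbors are identified geometrically (azimuthal order about the
    bundle's symmetry axis), not by chain label.  90 degrees each for an
    exact four-fold arrangement.
    """
    mask = (frame.atom_name == "CA") & (frame.res_id == residue)
    sub = frame.select(mask)
    chains = sorted(set(sub.chain_id))
    if len(chains) < 4:
        raise GeometryError(
            f"symmetry angles need residue {residue} C-alpha in >=4 chains, found {len(chains)}"
        )
    pts = np.array(
        [sub.coord[sub.chain_id == c][0] for c in chains], dtype=float
    )
    centroid = pts.mean(axis=0)
    rel = pts - centroid
    # plane normal = smallest-variance direction of the vertex cloud
    _, _, vt = np.linalg.svd(rel, full_matrices=False)
    normal = vt[-1]
    e1 = vt[0]
    e2 = np.cross(normal, e1)
    azimuth = np.arctan2(rel @ e2, rel @ e1)
    order = np.argsort(azimuth)
    pts = pts[order]
    n = len(pts)
    angles = np.empty(n)
    for i in range(n):
        v1 = pts[(i - 1) % n] - pts[i]
        v2 = pts[(i + 1) % n] - pts[i]
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        angles[i] = math.degrees(math.acos(float(np.clip(cosang, -1.0, 1.0))))
    # report in the original (sorted-chain) subunit order
    inv = np.empty(n, dtype=int)
    inv[order] = np.arange(n)
    return angles[inv]


def trajectory_stats(
    traj: Trajectory,
    observable: Callable[[Frame], float | np.ndarray],
    window_last_ns: float = 50.0,
    sample_every_ns: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Mean and sample SD of an observable over the final trajectory window.

    The observable is evaluated on the frame nearest each sample time of the
    inclusive grid ``[t_end - window, t_end]`` with spacing
    ``sample_every_ns`` (a 50 ns window sampled every 0.1 ns gives 501
    samples).  Returns (mean, SD with n-1 denominator, n_samples); mean/SD
    are arrays if the observable is vector-valued.
    """
    if window_last_ns <= 0 or sample_every_ns <= 0:
        raise GeometryError("window and sampling interval must be positive")
    t0, t1 = float(traj.times_ns[0]), float(traj.times_ns[-1])
    if t1 - t0 < window_last_ns - 1e-9:
        raise GeometryError(
            f"trajectory spans {t1 - t0:g} ns, shorter than the {window_last_ns:g} ns window"
        )
    n_samples = int(round(window_last_ns / sample_every_ns)) + 1
    sample_t = t1 - window_last_ns + np.arange(n_samples) * sample_every_ns
    idx = np.clip(np.searchsorted(traj.times_ns, sample_t), 0, traj.n_frames - 1)
    left = np.clip(idx - 1, 0, traj.n_frames - 1)
    nearer_left = np.abs(traj.times_ns[left] - sample_t) < np.abs(traj.times_ns[idx] - sample_t)
    idx = np.where(nearer_left, left, idx)
    cache: dict[int, np.ndarray] = {}
    values = []
    for i in idx:
        if i not in cache:
            cache[i] = np.atleast_1d(np.asarray(observable(traj.frame(int(i))), dtype=float))
        values.append(cache[i])
    arr = np.vstack(values)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1) if len(arr) > 1 else np.zeros(arr.shape[1])
    if mean.size == 1:
        return float(mean[0]), float(sd[0]), n_samples
    return mean, sd, n_samples
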