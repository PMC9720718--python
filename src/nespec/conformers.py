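"""Trajectory frames, sampling schedules, and torsional (circular) statistics.

A molecular-dynamics run of a flexible fluorophore is summarised here by the
geometric observables that control its photophysics: signed dihedral angles of
the substituents relative to the rigid chromophore core, and selected
interatomic distances.  Saved frames arrive as multi-frame XYZ text; angle
time series are binned into circular histograms whose modes identify the
thermally populated conformers.

Angles are degrees throughout, wrapped to the half-open interval (-180, +180]
with -180 mapped to +180 so that signed mode positions are unambiguous.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .errors import (
    DegenerateGeometryError,
    NoDataError,
    ParseError,
    UnknownAtomError,
)

__all__ = [
    "Frame",
    "DihedralSpec",
    "AngleSeries",
    "Mode",
    "AngularDistribution",
    "SamplingSchedule",
    "DEFAULT_DIHEDRALS",
    "DEFAULT_DISTANCE_PAIR",
    "wrap_angle",
    "circular_difference",
    "compute_dihedral",
    "compute_distance",
    "compute_angle_series",
    "saved_frame_times",
    "decimation_indices",
    "angular_histogram",
    "find_modes",
    "read_xyz_frames",
    "write_xyz_frames",
    "write_angle_series",
    "read_angle_series",
    "write_distribution",
]

# Torsions monitored for the xanthene probe: each quadruple rules the
# orientation of one peripheral substituent relative to the core.
DEFAULT_DIHEDRALS: dict[str, "DihedralSpec"] = {}

#: Terminal carbons of the two thioethyl chains (copper-binding arms).
DEFAULT_DISTANCE_PAIR: tuple[str, str] = ("C27", "C26")


def wrap_angle(angle_deg: float) -> float:
    """Wrap an angle in degrees to (-180, +180], mapping -180 to +180."""
    a = math.fmod(angle_deg, 360.0)
    if a > 180.0:
        a -= 360.0
    elif a <= -180.0:
        a += 360.0
    return a


def circular_difference(a_deg: float, b_deg: float) -> float:
    """Signed circular difference a - b in degrees, in (-180, +180]."""
    return wrap_angle(a_deg - b_deg)


@dataclass(frozen=True)
class Frame:
    """One saved configuration: labelled atoms with Cartesian coordinates in Å."""

    frame_index: int
    time_ps: float
    atom_labels: tuple[str, ...]
    coordinates: np.ndarray  # shape (n_atoms, 3), Å

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "atom_labels", tuple(self.atom_labels))
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        if self.time_ps < 0:
            raise ValueError("time_ps must be >= 0")
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        if coords.shape[0] != len(self.atom_labels):
            raise ValueError("coordinate count must equal label count")
        if len(set(self.atom_labels)) != len(self.atom_labels):
            raise ValueError("atom labels must be unique within a frame")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_labels)

    def position(self, label: str) -> np.ndarray:
        try:
            i = self.atom_labels.index(label)
        except ValueError:
            raise UnknownAtomError(
                f"unknown atom {label!r} in frame {self.frame_index}"
            ) from None
        return self.coordinates[i]


@dataclass(frozen=True)
class DihedralSpec:
    """A named torsion defined by an ordered quadruple of atom labels."""

    name: str
    atoms: tuple[str, str, str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "atoms", tuple(self.atoms))
        if len(self.atoms) != 4 or len(set(self.atoms)) != 4:
            raise ValueError("a dihedral needs four distinct atom labels")


DEFAULT_DIHEDRALS.update(
    {
        "delta": DihedralSpec("delta", ("C11", "C36", "C32", "C35")),
        "epsilon": DihedralSpec("epsilon", ("C04", "N28", "C29", "C07")),
        "zeta": DihedralSpec("zeta", ("C16", "N40", "C15", "C37")),
        "eta": DihedralSpec("eta", ("C18", "N40", "C15", "C37")),
    }
)


@dataclass(frozen=True)
class AngleSeries:
    """A dihedral's value along the trajectory, parallel to saved frame indices."""

    name: str
    values: tuple[float, ...]
    frame_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        object.__setattr__(self, "frame_indices", tuple(int(i) for i in self.frame_indices))
        if len(self.values) != len(self.frame_indices):
            raise ValueError("values and frame_indices must have equal length")
        for v in self.values:
            if not (-180.0 < v <= 180.0):
                raise ValueError(f"angle {v} outside (-180, 180]")

    def __len__(self) -> int:
        return len(self.values)

    def subset(self, indices: Sequence[int]) -> "AngleSeries":
        """Restrict to positions (not frame indices) given by ``indices``."""
        return AngleSeries(
            self.name,
            tuple(self.values[i] for i in indices),
            tuple(self.frame_indices[i] for i in indices),
        )


@dataclass(frozen=True)
class Mode:
    """A local maximum of a circular distribution."""

    center_deg: float
    half_width_uncertainty_deg: float
    density: float


@dataclass
class AngularDistribution:
    """Circular histogram of a torsion, normalised to unit integral over the circle."""

    bin_centers: np.ndarray  # degrees
    densities: np.ndarray  # per degree, sums (x bin_width) to 1
    bin_width: float
    modes: list[Mode] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.densities = np.asarray(self.densities, dtype=float)
        if self.bin_centers.shape != self.densities.shape:
            raise ValueError("bin_centers and densities must have equal shape")
        if np.any(self.densities < 0):
            raise ValueError("densities must be non-negative")
        total = float(np.sum(self.densities) * self.bin_width)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"densities must integrate to 1 over the circle, got {total}")


@dataclass(frozen=True)
class SamplingSchedule:
    """When frames were saved and how they are thinned for excited-state runs.

    ``duration_ps`` and ``save_interval_ps`` describe the production run
    (e.g. 5 ns saved every 4 ps gives 1250 post-initial frames);
    ``decimation_stride`` thins the saved frames for the expensive
    excited-state calculations (every 10th by default).  ``include_initial``
    decides whether the t=0 configuration counts as a saved frame.
    """

    duration_ps: float = 5000.0
    save_interval_ps: float = 4.0
    decimation_stride: int = 10
    include_initial: bool = True

    def __post_init__(self) -> None:
        if self.duration_ps < 0:
            raise ValueError("duration_ps must be >= 0")
        if self.save_interval_ps <= 0:
            raise ValueError("save_interval_ps must be > 0")
        if self.decimation_stride < 1:
            raise ValueError("decimation_stride must be >= 1")


# ---------------------------------------------------------------------------
# geometry


def _torsion_from_positions(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray
) -> float:
    """Signed torsion A-B-C-D in degrees via the two-plane atan2 formulation.

    Sign convention: with A=(0,1,0), B=(0,0,0), C=(1,0,0) and D obtained by
    rotating (1,1,0) about the B->C axis by +phi (right-hand rule), the torsion
    is +phi.  Equivalently, looking down B->C, a counter-clockwise rotation of
    the far bond relative to the near bond is positive.
    """
    b0 = a - b
    b1 = c - b
    b2 = d - c
    nb1 = np.linalg.norm(b1)
    if nb1 < 1e-12:
        raise DegenerateGeometryError("central bond B-C has zero length")
    b1 = b1 / nb1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    scale = max(np.linalg.norm(b0), np.linalg.norm(b2), 1e-12)
    if np.linalg.norm(v) < 1e-9 * scale or np.linalg.norm(w) < 1e-9 * scale:
        raise DegenerateGeometryError(
            "three consecutive atoms of the quadruple are collinear"
        )
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(b1, v), w))
    return wrap_angle(math.degrees(math.atan2(y, x)))


def compute_dihedral(frame: Frame, spec: DihedralSpec) -> float:
    """Signed dihedral angle (degrees, in (-180, 180]) for ``spec`` in ``frame``.

    Raises :class:`UnknownAtomError` if a label is absent and
    :class:`DegenerateGeometryError` if three consecutive atoms are collinear.
    """
    a, b, c, d = (frame.position(lbl) for lbl in spec.atoms)
    return _torsion_from_positions(a, b, c, d)


def compute_distance(frame: Frame, pair: Sequence[str]) -> float:
    """Euclidean distance in Å between two labelled atoms."""
    lbl_a, lbl_b = pair
    return float(np.linalg.norm(frame.position(lbl_a) - frame.position(lbl_b)))


def compute_angle_series(frames: Iterable[Frame], spec: DihedralSpec) -> AngleSeries:
    """Evaluate one dihedral across a list of frames."""
    values, indices = [], []
    for fr in frames:
        values.append(compute_dihedral(fr, spec))
        indices.append(fr.frame_index)
    if not values:
        raise NoDataError("no frames supplied")
    return AngleSeries(spec.name, tuple(values), tuple(indices))


# ---------------------------------------------------------------------------
# sampling schedules


def saved_frame_times(schedule: SamplingSchedule) -> list[float]:
    """Times (ps) of the saved frames: k·Δt for k = 1..⌊T/Δt⌋, with t=0 prepended
    iff the schedule includes the initial configuration."""
    n_saves = math.floor(schedule.duration_ps / schedule.save_interval_ps + 1e-9)
    times = [k * schedule.save_interval_ps for k in range(1, n_saves + 1)]
    if schedule.include_initial:
        times.insert(0, 0.0)
    return times


def decimation_indices(n_frames: int, stride: int, offset: int = 0) -> list[int]:
    """Indices of every ``stride``-th frame starting at ``offset``.

    With 1251 saved frames (t=0 plus 1250 saves) and stride 10 this yields the
    126 configurations passed on to the excited-state calculations.
    """
    if n_frames < 0:
        raise ValueError("n_frames must be >= 0")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if not (0 <= offset < stride):
        raise ValueError("offset must satisfy 0 <= offset < stride")
    return list(range(offset, n_frames, stride))


# ---------------------------------------------------------------------------
# circular statistics


def angular_histogram(series: AngleSeries, bin_width: float = 1.0) -> AngularDistribution:
    """Circular histogram of an angle series, normalised to unit integral.

    ``bin_width`` (degrees) must divide 360 evenly.  Bins tile (-180, 180];
    a value of exactly +180 lands in the last bin, so +/-180 is one circular
    point, not two.
    """
    if len(series) == 0:
        raise NoDataError("cannot histogram an empty angle series")
    n_bins_f = 360.0 / bin_width
    n_bins = round(n_bins_f)
    if abs(n_bins_f - n_bins) > 1e-9 or n_bins < 1:
        raise ValueError("bin_width must divide 360 evenly")
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    counts, _ = np.histogram(np.asarray(series.values), bins=edges)
    densities = counts / (len(series) * bin_width)
    centers = edges[:-1] + bin_width / 2.0
    return AngularDistribution(centers, densities, bin_width)


def find_modes(
    dist: AngularDistribution,
    min_separation_deg: float = 10.0,
    min_prominence_fraction: float = 0.1,
) -> list[Mode]:
    """Local maxima of the circular density, merged within ``min_separation_deg``.

    Candidate peaks are strict circular local maxima of a lightly smoothed
    density (5-bin circular moving average — a finite-sample histogram is
    Poisson-noisy at the few-percent level, which would otherwise jitter the
    argmax bin by several degrees).  Peaks below ``min_prominence_fraction``
    of the smoothed maximum are dropped; the rest are accepted greedily by
    descending density, skipping any closer (circularly) than
    ``min_separation_deg`` to an already accepted mode.  Each accepted center
    is then refined as the density-weighted circular mean of the raw bins
    within ``min_separation_deg`` of the peak and snapped to the nearest bin
    center, with half a bin width — the histogram resolution — as its
    position uncertainty.  The result is also stored on ``dist.modes``.
    """
    d = dist.densities
    n = len(d)
    if float(d.max(initial=0.0)) <= 0.0:
        dist.modes = []
        return []
    win = min(2, (n - 1) // 2)
    kernel = np.ones(2 * win + 1) / (2 * win + 1)
    smooth = np.convolve(np.concatenate([d[-win:], d, d[:win]]), kernel, mode="valid") if win else d
    # tile the density to make the circular wrap explicit for the peak finder
    tiled = np.concatenate([smooth, smooth, smooth])
    idx, _ = signal.find_peaks(tiled, height=min_prominence_fraction * smooth.max())
    candidates = sorted(
        {i - n for i in idx if n <= i < 2 * n},
        key=lambda i: (-smooth[i], dist.bin_centers[i]),
    )
    accepted: list[int] = []
    for i in candidates:
        if all(
            abs(circular_difference(dist.bin_centers[i], dist.bin_centers[j]))
            >= min_separation_deg
            for j in accepted
        ):
            accepted.append(i)
    modes = []
    for i in accepted:
        offsets = np.array(
            [circular_difference(c, dist.bin_centers[i]) for c in dist.bin_centers]
        )
        mask = np.abs(offsets) <= min_separation_deg
        weight = float(d[mask].sum())
        shift = float((d[mask] * offsets[mask]).sum() / weight) if weight > 0 else 0.0
        center = wrap_angle(dist.bin_centers[i] + shift)
        j = int(np.argmin(np.abs([circular_difference(center, c) for c in dist.bin_centers])))
        modes.append(Mode(float(dist.bin_centers[j]), dist.bin_width / 2.0, float(d[j])))
    # refinement can pull two candidates together; enforce min_separation on
    # the final centers, keeping the denser mode
    modes.sort(key=lambda m: (-m.density, m.center_deg))
    kept: list[Mode] = []
    for m in modes:
        if all(
            abs(circular_difference(m.center_deg, k.center_deg)) >= min_separation_deg
            for k in kept
        ):
            kept.append(m)
    dist.modes = kept
    return kept


# ---------------------------------------------------------------------------
# I/O

_TIME_RE = re.compile(r"t\s*=\s*([-+0-9.eE]+)")


def read_xyz_frames(path: str | Path) -> list[Frame]:
    """Read a multi-frame XYZ file.

    Dialect: per frame, an atom-count line, a comment line optionally carrying
    ``t= <ps>``, then one ``label x y z`` line per atom.  Labels are taken
    verbatim as atom identifiers.  Frames are numbered 0,1,2,... in file
    order; a missing time defaults to the frame index (in ps) so downstream
    code always has monotone times.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[Frame] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n_atoms = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"expected atom count, got {lines[i]!r}", i + 1) from None
        if i + 1 + n_atoms >= len(lines) + 1 and n_atoms > 0:
            raise ParseError("truncated frame", i + 1)
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        m = _TIME_RE.search(comment)
        time_ps = float(m.group(1)) if m else float(len(frames))
        labels: list[str] = []
        coords: list[list[float]] = []
        for j in range(i + 2, i + 2 + n_atoms):
            if j >= len(lines):
                raise ParseError("truncated frame", i + 1)
            parts = lines[j].split()
            if len(parts) < 4:
                raise ParseError(f"expected 'label x y z', got {lines[j]!r}", j + 1)
            labels.append(parts[0])
            try:
                coords.append([float(p) for p in parts[1:4]])
            except ValueError:
                raise ParseError(f"bad coordinate in {lines[j]!r}", j + 1) from None
        frames.append(Frame(len(frames), time_ps, tuple(labels), np.array(coords)))
        i += 2 + n_atoms
    return frames


def write_xyz_frames(frames: Sequence[Frame], path: str | Path) -> None:
    """Write frames in the multi-frame XYZ dialect read by :func:`read_xyz_frames`."""
    out = []
    for fr in frames:
        out.append(str(fr.n_atoms))
        out.append(f"frame {fr.frame_index} t= {fr.time_ps:.4f} ps")
        for lbl, (x, y, z) in zip(fr.atom_labels, fr.coordinates):
            out.append(f"{lbl} {x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(out) + "\n")


def write_angle_series(
    series: AngleSeries, path: str | Path, times_ps: Mapping[int, float] | None = None
) -> None:
    """Write (frame_index, time_ps, angle_deg) as a CSV table."""
    times = [times_ps.get(i, float("nan")) if times_ps else float("nan") for i in series.frame_indices]
    df = pd.DataFrame(
        {"frame_index": series.frame_indices, "time_ps": times, "angle_deg": series.values}
    )
    df.to_csv(path, index=False)


def read_angle_series(path: str | Path, name: str = "angle") -> AngleSeries:
    """Read an angle series written by :func:`write_angle_series`."""
    df = pd.read_csv(path)
    return AngleSeries(name, tuple(df["angle_deg"]), tuple(df["frame_index"]))


def write_distribution(dist: AngularDistribution, path: str | Path) -> None:
    """Write (bin_center, density) as a CSV table."""
    pd.DataFrame({"bin_center": dist.bin_centers, "density": dist.densities}).to_csv(
        path, index=False
    )
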