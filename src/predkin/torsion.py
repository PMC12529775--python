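"""Torsional accessibility of trajectories and 2D-PES barrier search.

Molecular-dynamics trajectories of the previtamin are reduced to the
(phi1, phi2) torsion pair of the triene; occupancy of the sixteen
quadrant-pair labels distinguishes the free molecule's unrestricted
flexibility from the confinement inside the cyclodextrin dimer, where
trajectories started in the reactive -c-c arrangement never leave it.

Interconversion barriers between conformer families are measured on a
periodic 2D potential-energy grid over (phi1, phi2) with a minimax
(widest-path) criterion: the barrier from A to B is the smallest, over all
8-connected paths, of the highest energy met on the path, relative to A's
basin minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .conformers import (
    ALL_LABELS,
    TorsionDefinition,
    TrieneLabel,
    classify_triene,
    compute_dihedral,
    wrap_angle,
)

__all__ = [
    "TorsionTrajectory",
    "Histogram2D",
    "PESGrid",
    "trajectory_torsions",
    "accessibility_report",
    "histogram2d",
    "minimax_barrier",
]


@dataclass
class TorsionTrajectory:
    """Time series of the two triene torsions, in degrees in (-180, 180]."""

    phi1: np.ndarray
    phi2: np.ndarray
    source: str = "synthetic"  # "free" | "encapsulated" | "synthetic"

    def __post_init__(self) -> None:
        self.phi1 = np.atleast_1d(np.asarray(self.phi1, float))
        self.phi2 = np.atleast_1d(np.asarray(self.phi2, float))
        if self.phi1.shape != self.phi2.shape or self.phi1.ndim != 1:
            raise ValueError("phi1 and phi2 must be equal-length 1-D series")
        if len(self.phi1) == 0:
            raise ValueError("empty trajectory")
        for name, series in (("phi1", self.phi1), ("phi2", self.phi2)):
            if np.any(series <= -180.0) or np.any(series > 180.0):
                raise ValueError(f"{name} angles must lie in (-180, 180]")

    @property
    def n_frames(self) -> int:
        return len(self.phi1)

    def labels(self) -> list[TrieneLabel]:
        return [classify_triene(a, b) for a, b in zip(self.phi1, self.phi2)]


def trajectory_torsions(
    frames: Sequence[tuple[Sequence[str], np.ndarray]],
    torsions: TorsionDefinition,
    source: str = "synthetic",
) -> TorsionTrajectory:
    """Per-frame (phi1, phi2) series of a multi-frame trajectory.

    ``frames`` is a sequence of (elements, Nx3 coordinates) pairs, as
    returned by :func:`predkin.io.read_xyz`.
    """
    if not frames:
        raise ValueError("trajectory has no frames")
    n_atoms = len(frames[0][0])
    torsions.validate_for(n_atoms)
    phi1, phi2 = [], []
    for i, (elements, coords) in enumerate(frames):
        coords = np.asarray(coords, float)
        if len(elements) != n_atoms or coords.shape != (n_atoms, 3):
            raise ValueError(f"frame {i}: inconsistent atom count")
        phi1.append(compute_dihedral(*(coords[j] for j in torsions.phi1_atoms)))
        phi2.append(compute_dihedral(*(coords[j] for j in torsions.phi2_atoms)))
    return TorsionTrajectory(np.array(phi1), np.array(phi2), source=source)


@dataclass
class AccessibilityReport:
    """Occupancy of the sixteen triene labels by one trajectory."""

    occupancy: dict[str, float]  # label -> fraction of frames
    visited: frozenset[TrieneLabel]
    n_frames: int
    floor: float

    @property
    def reactive_only(self) -> bool:
        """True when the trajectory never leaves the reactive arrangements."""
        return all(lab.reactive for lab in self.visited)


def accessibility_report(
    traj: TorsionTrajectory, floor: float = 0.0
) -> AccessibilityReport:
    """Occupancy fraction per triene label and the set of visited labels.

    A label counts as visited when its occupancy exceeds ``floor``
    (default: any frame at all).
    """
    counts: dict[str, int] = {str(lab): 0 for lab in sorted(ALL_LABELS, key=str)}
    for lab in traj.labels():
        counts[str(lab)] += 1
    n = traj.n_frames
    occupancy = {k: v / n for k, v in counts.items()}
    visited = frozenset(
        TrieneLabel.from_string(k) for k, v in occupancy.items() if v > floor
    )
    return AccessibilityReport(occupancy, visited, n, floor)


@dataclass
class Histogram2D:
    """Periodic 2D histogram of a torsion trajectory.

    Bin edges span (-180, 180] on both axes; an angle exactly on an edge
    falls in the bin whose left edge it is (right-open convention), and
    +180 deg lands in the last bin, which is its periodic image.
    """

    counts: np.ndarray  # (n_bins, n_bins), phi1 rows
    edges1: np.ndarray
    edges2: np.ndarray
    label_occupancy: dict[str, float]

    @property
    def n_frames(self) -> int:
        return int(self.counts.sum())


def histogram2d(traj: TorsionTrajectory, n_bins: int = 72) -> Histogram2D:
    """Bin a trajectory on a periodic (phi1, phi2) grid (default 5-deg bins)."""
    if n_bins < 4:
        raise ValueError("need at least 4 bins per axis")
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    counts, e1, e2 = np.histogram2d(traj.phi1, traj.phi2, bins=[edges, edges])
    report = accessibility_report(traj)
    return Histogram2D(
        counts=counts.astype(int),
        edges1=e1,
        edges2=e2,
        label_occupancy=report.occupancy,
    )


@dataclass
class PESGrid:
    """Relative energies (kcal/mol) on a regular periodic (phi1, phi2) grid.

    ``values[i, j]`` is the energy at (phi1[i], phi2[j]); the grid is
    normalised so its minimum is zero (barriers are gauge-invariant).
    """

    values: np.ndarray
    phi1: np.ndarray  # grid-point angles, degrees
    phi2: np.ndarray
    periodic: tuple[bool, bool] = (True, True)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.phi1 = np.asarray(self.phi1, float)
        self.phi2 = np.asarray(self.phi2, float)
        if self.values.shape != (len(self.phi1), len(self.phi2)):
            raise ValueError("values shape inconsistent with axis lengths")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("PES grid energies must be finite")
        self.values = self.values - self.values.min()

    @classmethod
    def from_function(
        cls,
        func,
        spacing: float = 5.0,
        periodic: tuple[bool, bool] = (True, True),
    ) -> "PESGrid":
        axis = np.arange(-180.0 + spacing, 180.0 + spacing / 2, spacing)
        p1, p2 = np.meshgrid(axis, axis, indexing="ij")
        return cls(np.asarray(func(p1, p2), float), axis, axis, periodic)

    def label_mask(self, label: TrieneLabel) -> np.ndarray:
        """Boolean mask of grid points whose (phi1, phi2) carry ``label``."""
        import warnings as _warnings

        mask = np.zeros(self.values.shape, dtype=bool)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # boundary grid points
            for i, a in enumerate(self.phi1):
                for j, b in enumerate(self.phi2):
                    mask[i, j] = classify_triene(wrap_angle(a), wrap_angle(b)) == label
        return mask


class _DisjointSet:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def _neighbors(i, j, shape, periodic):
    n1, n2 = shape
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            ii, jj = i + di, j + dj
            if periodic[0]:
                ii %= n1
            elif not 0 <= ii < n1:
                continue
            if periodic[1]:
                jj %= n2
            elif not 0 <= jj < n2:
                continue
            yield ii, jj


def minimax_barrier(
    grid: PESGrid,
    start: TrieneLabel | np.ndarray,
    end: TrieneLabel | np.ndarray,
) -> float:
    """Interconversion barrier between two regions of a torsional PES.

    Over all 8-connected (periodically wrapped) paths from the lowest grid
    point of the start region to any point of the end region, returns the
    minimum over paths of the maximum energy on the path, minus the start
    energy.  Computed by flooding cells in order of increasing energy with
    a union-find structure (equivalent to a widest-path search).

    ``start`` and ``end`` may be triene labels (regions are their quadrant
    pairs) or explicit boolean masks of grid shape.
    """
    start_mask = start if isinstance(start, np.ndarray) else grid.label_mask(start)
    end_mask = end if isinstance(end, np.ndarray) else grid.label_mask(end)
    for name, mask in (("start", start_mask), ("end", end_mask)):
        if mask.shape != grid.values.shape:
            raise ValueError(f"{name} mask shape mismatch")
        if not mask.any():
            raise ValueError(f"{name} region contains no grid points")
    values = grid.values
    n1, n2 = values.shape
    flat = values.ravel()
    start_energies = np.where(start_mask, values, np.inf)
    start_idx = int(np.argmin(start_energies))
    e_start = flat[start_idx]
    end_flat = np.flatnonzero(end_mask.ravel())
    if end_mask.ravel()[start_idx]:
        return 0.0

    dsu = _DisjointSet(n1 * n2)
    active = np.zeros(n1 * n2, dtype=bool)
    order = np.argsort(flat, kind="stable")
    levels = flat[order]
    pos = 0
    while pos < len(order):
        level = levels[pos]
        # activate the whole energy level before testing connectivity
        while pos < len(order) and levels[pos] == level:
            idx = int(order[pos])
            active[idx] = True
            i, j = divmod(idx, n2)
            for ii, jj in _neighbors(i, j, (n1, n2), grid.periodic):
                nidx = ii * n2 + jj
                if active[nidx]:
                    dsu.union(idx, nidx)
            pos += 1
        if active[start_idx]:
            root = dsu.find(start_idx)
            for e in end_flat:
                if active[e] and dsu.find(int(e)) == root:
                    return float(level - e_start)
    raise ValueError("end region unreachable from start region")
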