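"""Conformer data model, dihedral geometry and triene classification.

The thermal [1,7]-H shift that converts previtamin D into vitamin D is only
possible when the two single-bond torsions of the triene moiety (phi1 and
phi2) put the molecule in an s-cis/s-cis arrangement.  Each torsion is
classified into one of four quadrants:

    +c : [0, 90)      -c : [-90, 0)
    +t : [90, 180]    -t : (-180, -90)

and a conformer is *reactive* when both torsions fall in the same cis
quadrant, i.e. (+c,+c) or (-c,-c).  The quadrant boundaries are assigned by
the half-open scheme above so that classification is total on (-180, 180];
an angle landing exactly on a boundary emits a warning (a measure-zero case
that must not crash trajectory analysis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptySelectionError, GeometryError

__all__ = [
    "Conformer",
    "ConformerEnsemble",
    "TrieneLabel",
    "TorsionDefinition",
    "compute_dihedral",
    "classify_triene",
    "label_ensemble",
    "filter_by_label",
    "wrap_angle",
]

_QUADRANTS = ("+c", "+t", "-t", "-c")


def wrap_angle(angle: float | np.ndarray) -> float | np.ndarray:
    """Map an angle in degrees onto the canonical domain (-180, 180]."""
    wrapped = np.mod(np.asarray(angle, dtype=float) + 180.0, 360.0) - 180.0
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    if np.isscalar(angle) or np.ndim(angle) == 0:
        return float(wrapped)
    return wrapped


@dataclass(frozen=True)
class TrieneLabel:
    """Quadrant pair (q1, q2) describing a triene conformation.

    ``reactive`` is true exactly for the s-cis/s-cis arrangements (+c,+c)
    and (-c,-c), the two possible antarafacial H-transfer channels.
    """

    q1: str
    q2: str

    def __post_init__(self) -> None:
        for q in (self.q1, self.q2):
            if q not in _QUADRANTS:
                raise ValueError(f"unknown quadrant symbol {q!r}")

    @property
    def reactive(self) -> bool:
        return (self.q1, self.q2) in (("+c", "+c"), ("-c", "-c"))

    def __str__(self) -> str:
        return f"{self.q1}{self.q2}"

    @classmethod
    def from_string(cls, text: str) -> "TrieneLabel":
        text = text.strip()
        if len(text) != 4:
            raise ValueError(f"cannot parse triene label {text!r}")
        return cls(text[:2], text[2:])


#: The two reactive arrangements, (+) and (-) channels.
REACTIVE_LABELS = frozenset({TrieneLabel("+c", "+c"), TrieneLabel("-c", "-c")})

ALL_LABELS = frozenset(TrieneLabel(a, b) for a in _QUADRANTS for b in _QUADRANTS)


@dataclass(frozen=True)
class TorsionDefinition:
    """Atom quadruples (0-based) defining phi1 and phi2.

    In the previtamin-D numbering these are atoms 1-2-3-4 and 3-4-5-6 of
    the triene; manifests and the CLI accept 1-based indices and convert.
    """

    phi1_atoms: tuple[int, int, int, int]
    phi2_atoms: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        for name, quad in (("phi1", self.phi1_atoms), ("phi2", self.phi2_atoms)):
            if len(quad) != 4 or len(set(quad)) != 4:
                raise ValueError(f"{name} atom indices must be 4 distinct values")
            if any(i < 0 for i in quad):
                raise ValueError(f"{name} atom indices must be non-negative")

    def validate_for(self, n_atoms: int) -> None:
        for quad in (self.phi1_atoms, self.phi2_atoms):
            if max(quad) >= n_atoms:
                raise IndexError(
                    f"torsion atom index {max(quad)} out of range for {n_atoms} atoms"
                )

    @classmethod
    def from_one_based(
        cls, phi1: Sequence[int], phi2: Sequence[int]
    ) -> "TorsionDefinition":
        return cls(tuple(i - 1 for i in phi1), tuple(i - 1 for i in phi2))


def compute_dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle p1-p2-p3-p4 in degrees, in (-180, 180].

    IUPAC sign convention: looking from p1 toward p4 along the p2-p3 bond,
    a clockwise rotation of the far bond is positive.

    Raises
    ------
    GeometryError
        If either bonded triple is collinear (the plane normal vanishes)
        or consecutive points coincide.
    """
    pts = [np.asarray(p, dtype=float) for p in (p1, p2, p3, p4)]
    if any(not np.all(np.isfinite(p)) or p.shape != (3,) for p in pts):
        raise GeometryError("dihedral points must be finite 3-vectors")
    b1 = pts[1] - pts[0]
    b2 = pts[2] - pts[1]
    b3 = pts[3] - pts[2]
    scale = max(np.linalg.norm(b) for b in (b1, b2, b3))
    if scale == 0.0 or any(np.linalg.norm(b) < 1e-12 * scale for b in (b1, b2, b3)):
        raise GeometryError("coincident consecutive points in dihedral")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if (
        np.linalg.norm(n1) < 1e-10 * scale**2
        or np.linalg.norm(n2) < 1e-10 * scale**2
    ):
        raise GeometryError("collinear atoms: dihedral plane is undefined")
    angle = np.degrees(
        np.arctan2(np.dot(np.cross(n1, n2), b2) / np.linalg.norm(b2), np.dot(n1, n2))
    )
    return wrap_angle(float(angle))


def _quadrant(angle: float) -> str:
    if not -180.0 < angle <= 180.0:
        raise ValueError(f"angle {angle} outside (-180, 180]")
    if angle in (0.0, 90.0, -90.0, 180.0):
        warnings.warn(
            f"torsion angle exactly on a quadrant boundary ({angle} deg); "
            "assigned by the half-open convention",
            stacklevel=3,
        )
    if 0.0 <= angle < 90.0:
        return "+c"
    if 90.0 <= angle <= 180.0:
        return "+t"
    if -90.0 <= angle < 0.0:
        return "-c"
    return "-t"


def classify_triene(phi1: float, phi2: float) -> TrieneLabel:
    """Assign the quadrant-pair label of a (phi1, phi2) torsion pair."""
    return TrieneLabel(_quadrant(float(phi1)), _quadrant(float(phi2)))


@dataclass
class Conformer:
    """One stationary point: geometry, energy and Hessian.

    Energies are stored in kcal/mol relative to the ensemble reference;
    Hessians in kcal mol^-1 A^-2 (converted from hartree/bohr^2 on read).
    ``n_imag_expected`` is 0 for a minimum and 1 for a transition state.
    """

    id: str
    elements: tuple[str, ...]
    geometry: np.ndarray  # (N, 3) angstrom
    masses: np.ndarray  # (N,) amu
    energy: float  # kcal/mol, relative to ensemble reference
    hessian: np.ndarray | None = None  # (3N, 3N) kcal/mol/A^2
    n_imag_expected: int = 0
    symmetry_number: int = 1

    def __post_init__(self) -> None:
        self.elements = tuple(self.elements)
        self.geometry = np.asarray(self.geometry, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        n = len(self.elements)
        if n < 2:
            raise ValueError("a conformer needs at least 2 atoms")
        if self.geometry.shape != (n, 3):
            raise ValueError(f"geometry shape {self.geometry.shape} != ({n}, 3)")
        if not np.all(np.isfinite(self.geometry)):
            raise ValueError("geometry contains non-finite coordinates")
        if self.masses.shape != (n,) or np.any(self.masses <= 0):
            raise ValueError("masses must be positive, one per atom")
        if self.n_imag_expected not in (0, 1):
            raise ValueError("n_imag_expected must be 0 (minimum) or 1 (TS)")
        if self.symmetry_number < 1:
            raise ValueError("symmetry_number must be a positive integer")
        if self.hessian is not None:
            self.hessian = np.asarray(self.hessian, dtype=float)
            if self.hessian.shape != (3 * n, 3 * n):
                raise ValueError(
                    f"hessian shape {self.hessian.shape} != ({3 * n}, {3 * n})"
                )
            scale = np.abs(self.hessian).max()
            if scale > 0 and np.abs(self.hessian - self.hessian.T).max() > 1e-8 * scale:
                raise ValueError("hessian is not symmetric within 1e-8 relative")
            # store the exactly symmetrised matrix
            self.hessian = 0.5 * (self.hessian + self.hessian.T)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def torsion_angles(self, torsions: TorsionDefinition) -> tuple[float, float]:
        torsions.validate_for(self.n_atoms)
        phi1 = compute_dihedral(*(self.geometry[i] for i in torsions.phi1_atoms))
        phi2 = compute_dihedral(*(self.geometry[i] for i in torsions.phi2_atoms))
        return phi1, phi2


@dataclass
class ConformerEnsemble:
    """Role- and medium-tagged set of conformers sharing an energy reference.

    Member energies are relative to the most stable member (minimum exactly
    0); ``reference_energy`` keeps the absolute energy of that member so
    that barrier heights between ensembles remain computable.
    """

    conformers: list[Conformer]
    role: str  # "reactant" | "transition_state"
    medium: str = "free"  # "free" | "encapsulated"
    solvent: str = "gas"  # "gas" | "n-hexane" | "water"
    reference_energy: float = 0.0  # absolute energy of most stable member

    def __post_init__(self) -> None:
        if self.role not in ("reactant", "transition_state"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.medium not in ("free", "encapsulated"):
            raise ValueError(f"unknown medium {self.medium!r}")
        if not self.conformers:
            raise ValueError("ensemble must contain at least one conformer")
        n = self.conformers[0].n_atoms
        if any(c.n_atoms != n for c in self.conformers):
            raise ValueError("all conformers in an ensemble share one atom count")
        expected = 0 if self.role == "reactant" else 1
        for c in self.conformers:
            if c.n_imag_expected != expected:
                raise ValueError(
                    f"conformer {c.id!r}: n_imag_expected={c.n_imag_expected} "
                    f"inconsistent with role {self.role!r}"
                )
        shift = min(c.energy for c in self.conformers)
        if shift != 0.0:
            self.conformers = [replace(c, energy=c.energy - shift) for c in self.conformers]
            self.reference_energy = self.reference_energy + shift

    @property
    def n_atoms(self) -> int:
        return self.conformers[0].n_atoms

    def __len__(self) -> int:
        return len(self.conformers)

    def __iter__(self):
        return iter(self.conformers)


def label_ensemble(
    ensemble: ConformerEnsemble, torsions: TorsionDefinition
) -> pd.DataFrame:
    """Tabulate each conformer's torsions, triene label and relative energy.

    Returns one row per conformer with columns
    ``id, phi1, phi2, label, reactive, rel_energy``.
    """
    torsions.validate_for(ensemble.n_atoms)
    rows = []
    for c in ensemble:
        phi1, phi2 = c.torsion_angles(torsions)
        lab = classify_triene(phi1, phi2)
        rows.append(
            {
                "id": c.id,
                "phi1": phi1,
                "phi2": phi2,
                "label": str(lab),
                "reactive": lab.reactive,
                "rel_energy": c.energy,
            }
        )
    return pd.DataFrame(rows)


def filter_by_label(
    ensemble: ConformerEnsemble,
    allowed: Iterable[TrieneLabel | str],
    torsions: TorsionDefinition,
) -> ConformerEnsemble:
    """Restrict an ensemble to conformers whose triene label is allowed.

    This implements the encapsulation constraint: inside the cyclodextrin
    dimer only the -c-c arrangement is accessible, so rate calculations for
    the encapsulated system use ``filter_by_label(ens, {"-c-c"}, tors)``.

    The subset's energy reference is recomputed (its minimum becomes 0);
    the input ensemble is left untouched.

    Raises
    ------
    EmptySelectionError
        If no conformer carries an allowed label.
    """
    allowed_set = {
        lab if isinstance(lab, TrieneLabel) else TrieneLabel.from_string(lab)
        for lab in allowed
    }
    torsions.validate_for(ensemble.n_atoms)
    kept = [
        c
        for c in ensemble
        if classify_triene(*c.torsion_angles(torsions)) in allowed_set
    ]
    if not kept:
        raise EmptySelectionError(
            f"no conformer with label in {{{', '.join(sorted(map(str, allowed_set)))}}}"
        )
    # re-referencing happens in __post_init__; keep absolute bookkeeping
    return ConformerEnsemble(
        conformers=[replace(c) for c in kept],
        role=ensemble.role,
        medium=ensemble.medium,
        solvent=ensemble.solvent,
        reference_energy=ensemble.reference_energy,
    )
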