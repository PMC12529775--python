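"""Harmonic-oscillator / rigid-rotor rovibrational partition functions.

Per-conformer partition functions are combined into multistructural (MS)
sums over a conformer ensemble,

    Q^MS = sum_j q_rot,j * q_vib,j * exp(-dU_j / kB T),

with dU_j the energy of conformer j relative to the most stable member
(optionally zero-point corrected).  Every conformer contributes to the sum:
even when the most stable conformer is not the reactive one, its Boltzmann
weight still dilutes the reactive population, which is exactly the effect
the multistructural treatment captures.

This is the local-harmonic variant (MS-LH): no torsional-anharmonicity or
hindered-rotor corrections are applied, and every report records that
choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conformers import Conformer, ConformerEnsemble
from .constants import CODATA2018, DEFAULT_FREQUENCY_SCALE, PhysicalConstants
from .errors import GeometryError, StationaryPointError

__all__ = [
    "FrequencySet",
    "PartitionFunctionResult",
    "project_and_mass_weight",
    "harmonic_frequencies",
    "q_vib",
    "q_rot",
    "ms_partition",
    "zero_point_energy",
]

#: Threshold on the smallest principal moment of inertia (amu A^2) below
#: which a geometry is treated as linear (5 external modes instead of 6).
LINEARITY_MOMENT_THRESHOLD = 1e-8

#: Eigenvalue magnitude (mass-weighted, kcal/mol/A^2/amu) under which a
#: projected-out external mode is considered numerically zero.
PROJECTION_TOLERANCE = 1e-6

#: Internal frequencies below this magnitude (cm^-1) after projection
#: indicate an ill-conditioned Hessian and raise a warning.
CONDITIONING_WAVENUMBER = 1.0


@dataclass(frozen=True)
class FrequencySet:
    """Scaled harmonic wavenumbers of one conformer.

    ``real_wavenumbers`` are the positive internal-mode wavenumbers in
    cm^-1 (sorted ascending); ``imaginary_wavenumbers`` hold the magnitudes
    of imaginary modes (exactly one for a transition state).
    """

    real_wavenumbers: np.ndarray
    imaginary_wavenumbers: np.ndarray
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "real_wavenumbers", np.sort(np.asarray(self.real_wavenumbers, float))
        )
        object.__setattr__(
            self,
            "imaginary_wavenumbers",
            np.sort(np.asarray(self.imaginary_wavenumbers, float)),
        )
        if np.any(self.real_wavenumbers <= 0) or np.any(self.imaginary_wavenumbers <= 0):
            raise ValueError("wavenumber magnitudes must be positive")

    @property
    def n_imag(self) -> int:
        return len(self.imaginary_wavenumbers)


def external_mode_basis(
    geometry: np.ndarray, masses: np.ndarray, tol: float = 1e-10
) -> np.ndarray:
    """Orthonormal mass-weighted translation/rotation vectors, (3N, k).

    k is 5 for a linear geometry, 6 otherwise (3 for a hypothetical
    point, which is rejected upstream).
    """
    geometry = np.asarray(geometry, float)
    masses = np.asarray(masses, float)
    n = len(masses)
    sqm = np.sqrt(masses)
    com = (masses[:, None] * geometry).sum(axis=0) / masses.sum()
    disp = geometry - com
    vecs = []
    for axis in range(3):
        t = np.zeros((n, 3))
        t[:, axis] = sqm
        vecs.append(t.ravel())
    for axis in range(3):
        e = np.zeros(3)
        e[axis] = 1.0
        r = np.cross(disp, e) * sqm[:, None]
        vecs.append(r.ravel())
    basis = []
    for v in vecs:
        for b in basis:
            v = v - b * (b @ v)
        norm = np.linalg.norm(v)
        if norm > tol * np.sqrt(masses.sum()):
            basis.append(v / norm)
    return np.array(basis).T


def _moments_of_inertia(geometry: np.ndarray, masses: np.ndarray) -> np.ndarray:
    geometry = np.asarray(geometry, float)
    masses = np.asarray(masses, float)
    com = (masses[:, None] * geometry).sum(axis=0) / masses.sum()
    d = geometry - com
    inertia = np.einsum("i,ij,ik->jk", masses, d, d)
    inertia = np.trace(inertia) * np.eye(3) - inertia
    return np.sort(np.linalg.eigvalsh(inertia))


def n_external_modes(geometry: np.ndarray, masses: np.ndarray) -> int:
    """5 for a linear geometry, 6 otherwise (inertia test, 1e-8 amu A^2)."""
    moments = _moments_of_inertia(geometry, masses)
    return 5 if moments[0] < LINEARITY_MOMENT_THRESHOLD else 6


def project_and_mass_weight(
    hessian: np.ndarray,
    masses: np.ndarray,
    geometry: np.ndarray,
    n_project: int | None = None,
) -> np.ndarray:
    """Mass-weight a Cartesian Hessian and project out external modes.

    The returned matrix is P H_mw P with P the projector onto the
    complement of the mass-weighted translation/rotation space; it has
    ``n_project`` eigenvalues of magnitude below the projection tolerance,
    the rest being the internal-mode spectrum.
    """
    hessian = np.asarray(hessian, float)
    masses = np.asarray(masses, float)
    geometry = np.asarray(geometry, float)
    n = len(masses)
    if hessian.shape != (3 * n, 3 * n):
        raise ValueError("hessian/mass size mismatch")
    if geometry.shape != (n, 3):
        raise ValueError("geometry/mass size mismatch")
    scale = np.abs(hessian).max()
    if scale > 0 and np.abs(hessian - hessian.T).max() > 1e-8 * scale:
        raise ValueError("hessian is not symmetric")
    if n_project is None:
        n_project = n_external_modes(geometry, masses)
    if n_project not in (5, 6):
        raise ValueError("n_project must be 5 (linear) or 6")
    sqm = np.repeat(np.sqrt(masses), 3)
    h_mw = hessian / np.outer(sqm, sqm)
    basis = external_mode_basis(geometry, masses)
    if basis.shape[1] != n_project:
        raise GeometryError(
            f"found {basis.shape[1]} external modes, expected {n_project}"
        )
    proj = np.eye(3 * n) - basis @ basis.T
    return proj @ (0.5 * (h_mw + h_mw.T)) @ proj


def harmonic_frequencies(
    conformer: Conformer,
    scale_factor: float = DEFAULT_FREQUENCY_SCALE,
    constants: PhysicalConstants = CODATA2018,
    check_imag: bool = True,
) -> FrequencySet:
    """Scaled harmonic wavenumbers of a conformer from its Hessian.

    Mass-weighted eigenvalues lambda become wavenumbers
    nu = sign(lambda) * sqrt(|lambda|) / (2 pi c), then are multiplied by
    ``scale_factor``.  The external (translation/rotation) eigenvalues are
    removed by projection; the count of imaginary modes must match the
    conformer's declared stationary-point type.
    """
    if conformer.hessian is None:
        raise ValueError(f"conformer {conformer.id!r} has no Hessian")
    n_project = n_external_modes(conformer.geometry, conformer.masses)
    projected = project_and_mass_weight(
        conformer.hessian, conformer.masses, conformer.geometry, n_project
    )
    eigvals = np.linalg.eigvalsh(projected)
    # discard the n_project eigenvalues closest to zero (the projected-out
    # external modes)
    order = np.argsort(np.abs(eigvals))
    external = eigvals[order[:n_project]]
    internal = eigvals[order[n_project:]]
    if np.abs(external).max(initial=0.0) > PROJECTION_TOLERANCE:
        warnings.warn(
            "projected external eigenvalues exceed the projection tolerance "
            f"(max |lambda| = {np.abs(external).max():.3e})",
            stacklevel=2,
        )
    omega = np.sqrt(np.abs(internal) * constants.hessian_eigval_to_s2)
    wavenumbers = np.sign(internal) * omega / (2.0 * np.pi * constants.c_cm)
    wavenumbers = wavenumbers * scale_factor
    real = wavenumbers[wavenumbers > 0]
    imag = -wavenumbers[wavenumbers <= 0]
    if real.size and real.min() < CONDITIONING_WAVENUMBER:
        warnings.warn(
            f"internal frequency below {CONDITIONING_WAVENUMBER} cm^-1 "
            f"({real.min():.3g} cm^-1): Hessian may be ill-conditioned",
            stacklevel=2,
        )
    if check_imag and len(imag) != conformer.n_imag_expected:
        raise StationaryPointError(
            f"conformer {conformer.id!r}: found {len(imag)} imaginary modes, "
            f"expected {conformer.n_imag_expected} (mislabeled manifest row?)"
        )
    return FrequencySet(real, imag, scale_factor)


def zero_point_energy(
    freqs: FrequencySet, constants: PhysicalConstants = CODATA2018
) -> float:
    """Harmonic ZPE in kcal/mol (real modes only)."""
    return 0.5 * constants.wavenumber_to_kcalmol * float(freqs.real_wavenumbers.sum())


def q_vib(
    freqs: FrequencySet, T: float, constants: PhysicalConstants = CODATA2018
) -> float:
    """ZPE-referenced harmonic vibrational partition function.

    q = prod_i [1 - exp(-h c nu_i / kB T)]^-1 over the real modes; the
    imaginary mode of a transition state does not enter the product.
    The energy zero is the conformer's own ZPE, so q -> 1 as T -> 0.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    theta = constants.wavenumber_to_kcalmol * freqs.real_wavenumbers / (
        constants.kB * T
    )
    return float(np.exp(-np.sum(np.log1p(-np.exp(-theta)))))


def q_rot(
    geometry: np.ndarray,
    masses: np.ndarray,
    symmetry_number: int = 1,
    T: float = 298.15,
    constants: PhysicalConstants = CODATA2018,
) -> float:
    """Classical rigid-rotor partition function from principal moments.

    Nonlinear: q = sqrt(pi) / sigma * (T^3 / (Th_A Th_B Th_C))^(1/2) with
    rotational temperatures Th_i = hbar^2 / (2 I_i kB).  Linear geometries
    use the single-moment formula q = T / (sigma Th).
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    masses = np.asarray(masses, float)
    if len(masses) < 2:
        raise GeometryError("a single atom has no rotational partition function")
    if symmetry_number < 1:
        raise ValueError("symmetry number must be a positive integer")
    moments_si = (
        _moments_of_inertia(geometry, masses) * constants.amu_to_kg * 1e-20
    )  # kg m^2
    hbar = constants.h_SI / (2.0 * np.pi)
    if moments_si[0] / moments_si[-1] < 1e-12 or _moments_of_inertia(
        geometry, masses
    )[0] < LINEARITY_MOMENT_THRESHOLD:
        theta = hbar**2 / (2.0 * moments_si[-1] * constants.kB_SI)
        return float(T / (symmetry_number * theta))
    thetas = hbar**2 / (2.0 * moments_si * constants.kB_SI)
    return float(np.sqrt(np.pi) / symmetry_number * np.sqrt(T**3 / np.prod(thetas)))


@dataclass
class PartitionFunctionResult:
    """Multistructural rovibrational partition function of an ensemble.

    ``Q`` is the Boltzmann-weighted sum of per-conformer q_rot * q_vib
    contributions; the per-conformer table records each term.  ``variant``
    documents that the sum is local-harmonic (MS-LH).
    """

    Q: float
    T: float
    per_conformer: pd.DataFrame
    zpe_in_weights: bool
    scale_factor: float
    n_conformers_included: int
    zpe_reference: float  # ZPE of the weight-reference conformer (kcal/mol)
    variant: str = "MS-LH"

    @property
    def ln_Q(self) -> float:
        return float(np.log(self.Q))


def ms_partition(
    ensemble: ConformerEnsemble,
    T: float,
    scale_factor: float = DEFAULT_FREQUENCY_SCALE,
    zpe_in_weights: bool = True,
    constants: PhysicalConstants = CODATA2018,
) -> PartitionFunctionResult:
    """Multistructural partition function Q^MS of a conformer ensemble.

    Q^MS = sum_j q_rot,j q_vib,j exp(-dU_j / kB T), where dU_j is conformer
    j's energy relative to the most stable member.  With ``zpe_in_weights``
    (the default) the weights use ZPE-corrected energies U_j + ZPE_j, which
    keeps q_vib ZPE-referenced per conformer while accounting for ZPE
    differences across the ensemble.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    rows = []
    for c in ensemble:
        freqs = harmonic_frequencies(c, scale_factor, constants)
        zpe = zero_point_energy(freqs, constants)
        rows.append(
            {
                "id": c.id,
                "energy": c.energy,
                "zpe": zpe,
                "q_rot": q_rot(c.geometry, c.masses, c.symmetry_number, T, constants),
                "q_vib": q_vib(freqs, T, constants),
                "n_imag": freqs.n_imag,
            }
        )
    table = pd.DataFrame(rows)
    effective = table["energy"] + (table["zpe"] if zpe_in_weights else 0.0)
    ref_idx = int(np.argmin(effective.to_numpy()))
    dU = effective - effective.iloc[ref_idx]
    table["dU"] = dU
    table["weight"] = np.exp(-dU / constants.thermal_energy(T))
    table["contribution"] = table["q_rot"] * table["q_vib"] * table["weight"]
    table["cumulative_Q"] = table["contribution"].cumsum()
    return PartitionFunctionResult(
        Q=float(table["contribution"].sum()),
        T=T,
        per_conformer=table,
        zpe_in_weights=zpe_in_weights,
        scale_factor=scale_factor,
        n_conformers_included=len(table),
        zpe_reference=float(table["zpe"].iloc[ref_idx]),
    )
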