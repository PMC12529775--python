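"""Synthetic conformers, host-guest systems, trajectories and PES grids.

Every generator plants its ground truth — eigenvalue spectra, torsion
angles, cluster sizes, barrier heights, partition-function factors — so
each analysis stage can be tested end-to-end without external data.

Hessians are assembled in mass-weighted coordinates as
U diag(lambda) U^T, with U a seeded random orthogonal completion of the
exact translation/rotation basis at the generated geometry; the
normal-mode engine therefore recovers the planted spectrum exactly.
Fixtures are spectrally realistic (frequency ranges, imaginary-mode
counts, energy spacings), not structurally realistic: no attempt is made
to generate chemically sensible cyclodextrin geometries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .conformers import (
    Conformer,
    ConformerEnsemble,
    TorsionDefinition,
    TrieneLabel,
    classify_triene,
)
from .constants import BODY_TEMPERATURE_K, CODATA2018, PhysicalConstants
from .errors import GeometryError, StationaryPointError
from .factorization import HostGuestPartition, SubsystemQs
from .torsion import PESGrid, TorsionTrajectory

__all__ = [
    "EnsembleSpec",
    "HostGuestSpec",
    "make_conformer",
    "make_ensemble",
    "make_host_guest",
    "make_torsion_trajectory",
    "make_pes_grid",
    "make_catalysis_study",
    "chain_geometry",
    "quadrant_well",
    "DEFAULT_TORSIONS",
]

#: Torsion definition matching the 6-atom triene backbone that every
#: generated guest begins with (atoms 1-2-3-4 and 3-4-5-6, 0-based).
DEFAULT_TORSIONS = TorsionDefinition((0, 1, 2, 3), (2, 3, 4, 5))

_ATOM_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999}


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def chain_geometry(
    phi1: float,
    phi2: float,
    n_atoms: int = 6,
    seed: int | np.random.Generator = 0,
    bond: float = 1.45,
    angle: float = 120.0,
) -> np.ndarray:
    """Chain geometry whose first two backbone torsions are phi1, phi2.

    Atoms 0..5 are placed by internal coordinates (fixed bond length and
    bond angle) such that the 1-2-3-4 torsion equals ``phi1`` and the
    3-4-5-6 torsion equals ``phi2`` (1-based atom numbering, i.e. the
    default torsion definition).  Additional atoms are attached at seeded
    pseudo-random torsions.
    """
    if n_atoms < 6:
        raise ValueError("need at least the 6 triene backbone atoms")
    rng = _rng(seed)
    # torsion k is about bond (k+1)-(k+2): torsion list for atoms 3..n-1
    torsions = [phi1, 155.0, phi2]  # middle torsion fixed anti-like
    torsions += list(rng.uniform(-150.0, 150.0, n_atoms - 6))
    coords = np.zeros((n_atoms, 3))
    coords[1] = [bond, 0.0, 0.0]
    theta = math.radians(180.0 - angle)
    coords[2] = coords[1] + bond * np.array([math.cos(theta), math.sin(theta), 0.0])
    for k, tor in enumerate(torsions):
        a, b, c = coords[k], coords[k + 1], coords[k + 2]
        coords[k + 3] = _place_atom(a, b, c, bond, angle, tor)
    return coords


def _place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Natural extension reference frame (NeRF) placement of atom d such
    that |cd| = bond, angle(b,c,d) = angle and dihedral(a,b,c,d) = torsion."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = math.radians(angle)
    tor = math.radians(torsion)
    d_local = bond * np.array(
        [-math.cos(ang), math.sin(ang) * math.cos(tor), math.sin(ang) * math.sin(tor)]
    )
    # torsion sign: positive torsion rotates clockwise seen from a toward d
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _random_orthogonal_completion(
    basis: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Orthonormal columns spanning the complement of ``basis`` columns,
    drawn by seeded QR of a standard-normal matrix."""
    dim, k = basis.shape
    raw = rng.standard_normal((dim, dim - k))
    raw = raw - basis @ (basis.T @ raw)
    q, r = np.linalg.qr(raw)
    # fix QR sign ambiguity for determinism across BLAS builds
    q = q * np.sign(np.diag(r))
    return q


def _wavenumbers_to_eigvals(
    wavenumbers: np.ndarray, constants: PhysicalConstants
) -> np.ndarray:
    """Inverse of the frequency conversion: cm^-1 -> mass-weighted
    eigenvalue (kcal/mol/A^2/amu).  Negative input = imaginary mode."""
    wavenumbers = np.asarray(wavenumbers, float)
    omega = 2.0 * math.pi * constants.c_cm * np.abs(wavenumbers)
    return np.sign(wavenumbers) * omega**2 / constants.hessian_eigval_to_s2


def planted_hessian(
    geometry: np.ndarray,
    masses: np.ndarray,
    wavenumbers: np.ndarray,
    seed: int | np.random.Generator,
    constants: PhysicalConstants = CODATA2018,
) -> np.ndarray:
    """Cartesian Hessian whose normal-mode spectrum is exactly ``wavenumbers``.

    Built as U diag(lambda) U^T in mass-weighted coordinates with U a
    random orthogonal completion of the exact external-mode basis, then
    un-mass-weighted.
    """
    from .partition import external_mode_basis, n_external_modes

    rng = _rng(seed)
    masses = np.asarray(masses, float)
    n = len(masses)
    n_ext = n_external_modes(geometry, masses)
    wavenumbers = np.asarray(wavenumbers, float)
    if len(wavenumbers) != 3 * n - n_ext:
        raise ValueError(
            f"planted spectrum has {len(wavenumbers)} modes, "
            f"need {3 * n - n_ext} for {n} atoms"
        )
    basis = external_mode_basis(geometry, masses)
    modes = _random_orthogonal_completion(basis, rng)
    eigvals = _wavenumbers_to_eigvals(wavenumbers, constants)
    h_mw = modes @ np.diag(eigvals) @ modes.T
    sqm = np.repeat(np.sqrt(masses), 3)
    h = h_mw * np.outer(sqm, sqm)
    return 0.5 * (h + h.T)


@dataclass
class EnsembleSpec:
    """Recipe for a synthetic conformer ensemble with planted ground truth."""

    angles: list[tuple[float, float]]  # planted (phi1, phi2) per conformer
    energies: list[float]  # relative energies, kcal/mol
    spectra: list[np.ndarray]  # planted wavenumbers per conformer (cm^-1)
    role: str = "reactant"
    n_atoms: int = 6
    seed: int = 0
    medium: str = "free"
    solvent: str = "gas"

    def __post_init__(self) -> None:
        if not len(self.angles) == len(self.energies) == len(self.spectra):
            raise ValueError("angles, energies and spectra must align")
        n_imag = 1 if self.role == "transition_state" else 0
        for spec in self.spectra:
            if int(np.sum(np.asarray(spec) < 0)) != n_imag:
                raise ValueError(
                    f"each {self.role} spectrum must contain exactly {n_imag} "
                    "negative (imaginary) entries"
                )

    @property
    def labels(self) -> list[TrieneLabel]:
        return [classify_triene(a, b) for a, b in self.angles]


def make_conformer(
    wavenumbers: np.ndarray,
    seed: int | np.random.Generator,
    conformer_id: str = "c0",
    n_atoms: int | None = None,
    geometry: np.ndarray | None = None,
    elements: tuple[str, ...] | None = None,
    energy: float = 0.0,
    constants: PhysicalConstants = CODATA2018,
) -> Conformer:
    """Conformer with a planted harmonic spectrum.

    The number of negative entries in ``wavenumbers`` fixes the
    stationary-point type (0 = minimum, 1 = transition state).
    """
    rng = _rng(seed)
    wavenumbers = np.asarray(wavenumbers, float)
    if geometry is None:
        if n_atoms is None:
            n_atoms = (len(wavenumbers) + 6) // 3
        geometry = rng.uniform(-2.5, 2.5, (n_atoms, 3))
    geometry = np.asarray(geometry, float)
    n_atoms = len(geometry)
    if elements is None:
        elements = tuple(rng.choice(["C", "C", "C", "O", "H"]) for _ in range(n_atoms))
    masses = np.array([_ATOM_MASSES[e] for e in elements])
    hessian = planted_hessian(geometry, masses, wavenumbers, rng, constants)
    n_imag = int(np.sum(wavenumbers < 0))
    if n_imag > 1:
        raise StationaryPointError("at most one planted imaginary mode is allowed")
    return Conformer(
        id=conformer_id,
        elements=elements,
        geometry=geometry,
        masses=masses,
        energy=energy,
        hessian=hessian,
        n_imag_expected=n_imag,
    )


def make_ensemble(spec: EnsembleSpec) -> ConformerEnsemble:
    """Synthetic ensemble whose torsions, energies and spectra are planted."""
    rng = _rng(spec.seed)
    conformers = []
    for i, ((phi1, phi2), energy, spectrum) in enumerate(
        zip(spec.angles, spec.energies, spec.spectra)
    ):
        geometry = chain_geometry(phi1, phi2, spec.n_atoms, rng)
        conformers.append(
            make_conformer(
                spectrum,
                rng,
                conformer_id=f"{spec.role[0]}{i:02d}",
                geometry=geometry,
                elements=("C",) * spec.n_atoms,
                energy=energy,
            )
        )
    return ConformerEnsemble(
        conformers=conformers,
        role=spec.role,
        medium=spec.medium,
        solvent=spec.solvent,
    )


# ---------------------------------------------------------------------------
# host-guest systems


@dataclass
class HostGuestSpec:
    """Recipe for a synthetic host-guest system.

    ``coupling`` scales isotropic springs connecting seeded guest-host
    atom pairs; coupling = 0 gives an exactly block-diagonal Hessian and a
    planted f_coup of 1.
    """

    guest_spectrum: np.ndarray  # cm^-1, 3Ng-6 values (one may be negative)
    host_spectrum: np.ndarray  # cm^-1, 3Nh-6 values, all positive
    n_guest: int = 6
    n_host: int = 8
    coupling: float = 0.0  # spring constant scale, kcal/mol/A^2
    n_springs: int = 4
    seed: int = 0


@dataclass
class HostGuestSystem:
    """A generated host-guest complex plus its planted ground truth."""

    conformer: Conformer  # full system
    partition: HostGuestPartition
    blocks_truth: dict  # planted block matrices and geometries
    guest: Conformer  # the isolated guest (same block Hessian)


def make_host_guest(spec: HostGuestSpec) -> HostGuestSystem:
    """Assemble a full Hessian from planted blocks plus scaled coupling.

    The guest and host blocks are isolated-molecule Hessians with planted
    spectra; ``spec.coupling`` adds isotropic springs between seeded
    guest-host atom pairs (with the compensating diagonal terms, so the
    overall translations stay exact zero modes).  Coupling strong enough
    to create spurious negative full-system modes is rejected.
    """
    rng = _rng(spec.seed)
    ng, nh = spec.n_guest, spec.n_host
    guest_geom = chain_geometry(54.0, 43.0, ng, rng)
    host_geom = rng.uniform(-3.0, 3.0, (nh, 3)) + np.array([6.0, 0.0, 0.0])
    guest_elements = ("C",) * ng
    host_elements = ("O",) * nh
    guest_masses = np.array([_ATOM_MASSES[e] for e in guest_elements])
    host_masses = np.array([_ATOM_MASSES[e] for e in host_elements])
    F_guest = planted_hessian(guest_geom, guest_masses, spec.guest_spectrum, rng)
    F_host = planted_hessian(host_geom, host_masses, spec.host_spectrum, rng)
    n = ng + nh
    F = np.zeros((3 * n, 3 * n))
    F[: 3 * ng, : 3 * ng] = F_guest
    F[3 * ng :, 3 * ng :] = F_host
    if spec.coupling > 0.0:
        n_springs = min(spec.n_springs, ng, nh)
        if n_springs < 3:
            raise ValueError("need >= 3 springs to restore all intermolecular modes")
        pairs = zip(
            rng.choice(ng, n_springs, replace=False),
            rng.choice(nh, n_springs, replace=False),
        )
        for a, b in sorted((int(a), int(b)) for a, b in pairs):
            k = spec.coupling * float(rng.uniform(0.5, 1.5))
            ia, ib = 3 * a, 3 * (ng + b)
            for axis in range(3):
                F[ia + axis, ia + axis] += k
                F[ib + axis, ib + axis] += k
                F[ia + axis, ib + axis] -= k
                F[ib + axis, ia + axis] -= k
    geometry = np.vstack([guest_geom, host_geom])
    elements = guest_elements + host_elements
    masses = np.concatenate([guest_masses, host_masses])
    n_imag_expected = int(np.sum(np.asarray(spec.guest_spectrum) < 0))
    # reject couplings that corrupt the planted stationary-point type
    from .partition import project_and_mass_weight

    eigvals = np.linalg.eigvalsh(project_and_mass_weight(F, masses, geometry, 6))
    n_neg = int(np.sum(eigvals < -1e-6))
    if n_neg != n_imag_expected:
        raise ValueError(
            f"coupling {spec.coupling} produced {n_neg} negative full-system "
            f"modes (expected {n_imag_expected}); reduce the coupling"
        )
    conformer = Conformer(
        id="hostguest",
        elements=elements,
        geometry=geometry,
        masses=masses,
        energy=0.0,
        hessian=F,
        n_imag_expected=n_imag_expected,
    )
    guest = Conformer(
        id="guest",
        elements=guest_elements,
        geometry=guest_geom,
        masses=guest_masses,
        energy=0.0,
        hessian=F_guest,
        n_imag_expected=n_imag_expected,
    )
    partition = HostGuestPartition(tuple(range(ng)), tuple(range(ng, ng + nh)))
    # ground-truth blocks are the diagonal sub-blocks of the *final* F:
    # the spring compensation terms belong to the embedded subsystems,
    # exactly as a block slice of the encapsulated Hessian would see them
    truth = {
        "F_guest": F[: 3 * ng, : 3 * ng].copy(),
        "F_host": F[3 * ng :, 3 * ng :].copy(),
        "guest_geometry": guest_geom,
        "host_geometry": host_geom,
        "guest_masses": guest_masses,
        "host_masses": host_masses,
    }
    return HostGuestSystem(conformer, partition, truth, guest)


# ---------------------------------------------------------------------------
# reference thermochemistry (generator-side oracle, independent code path)


def _reference_q_rovib(
    hessian: np.ndarray,
    geometry: np.ndarray,
    masses: np.ndarray,
    T: float,
    scale: float = 1.0,
    include_rotation: bool = True,
    mode_floor_cm: float = 0.1,
    constants: PhysicalConstants = CODATA2018,
) -> tuple[float, float]:
    """(q_rovib, zpe) by brute force: SVD-based projector + scipy eigh.

    Deliberately written as a separate code path from
    :mod:`predkin.partition` so generator ground truths act as oracles.
    """
    masses = np.asarray(masses, float)
    n = len(masses)
    sqm = np.sqrt(masses)
    com = (masses[:, None] * geometry).sum(0) / masses.sum()
    disp = geometry - com
    ext = []
    for axis in range(3):
        t = np.zeros((n, 3))
        t[:, axis] = sqm
        ext.append(t.ravel())
        e = np.zeros(3)
        e[axis] = 1.0
        ext.append((np.cross(disp, e) * sqm[:, None]).ravel())
    ext_mat = np.array(ext).T
    u, s, _ = np.linalg.svd(ext_mat, full_matrices=True)
    rank = int(np.sum(s > 1e-10 * s[0]))
    proj = np.eye(3 * n) - u[:, :rank] @ u[:, :rank].T
    h_mw = hessian / np.outer(np.repeat(sqm, 3), np.repeat(sqm, 3))
    eigvals = scipy.linalg.eigh(proj @ h_mw @ proj, eigvals_only=True)
    order = np.argsort(np.abs(eigvals))
    internal = eigvals[order[rank:]]
    wn = (
        np.sign(internal)
        * np.sqrt(np.abs(internal) * constants.hessian_eigval_to_s2)
        / (2 * math.pi * constants.c_cm)
        * scale
    )
    wn = wn[np.abs(wn) >= mode_floor_cm]
    real = wn[wn > 0]
    zpe = 0.5 * constants.wavenumber_to_kcalmol * real.sum()
    theta = constants.wavenumber_to_kcalmol * real / (constants.kB * T)
    qv = float(np.prod(1.0 / (1.0 - np.exp(-theta))))
    if not include_rotation:
        return qv, zpe
    inertia = np.einsum("i,ij,ik->jk", masses, disp, disp)
    inertia = np.trace(inertia) * np.eye(3) - inertia
    moments = np.sort(scipy.linalg.eigvalsh(inertia)) * constants.amu_to_kg * 1e-20
    hbar = constants.h_SI / (2 * math.pi)
    if moments[0] < 1e-8 * constants.amu_to_kg * 1e-20:
        qr = T * 2 * moments[-1] * constants.kB_SI / hbar**2
    else:
        thetas = hbar**2 / (2 * moments * constants.kB_SI)
        qr = math.sqrt(math.pi) * math.sqrt(T**3 / np.prod(thetas))
    return qr * qv, zpe


def _reference_ms_q(
    ensemble: ConformerEnsemble,
    T: float,
    scale: float,
    zpe_in_weights: bool = True,
    constants: PhysicalConstants = CODATA2018,
) -> float:
    terms = []
    for c in ensemble:
        q, zpe = _reference_q_rovib(
            c.hessian, c.geometry, c.masses, T, scale, constants=constants
        )
        terms.append((q, c.energy + (zpe if zpe_in_weights else 0.0)))
    ref = min(e for _, e in terms)
    kT = constants.thermal_energy(T)
    return float(sum(q * math.exp(-(e - ref) / kT) for q, e in terms))


# ---------------------------------------------------------------------------
# torsional trajectories and PES grids


def quadrant_well(label: TrieneLabel | str, depth: float = 0.0):
    """Potential that is ``depth`` inside a quadrant pair, infinite outside.

    Models the hard confinement of the cyclodextrin cavity: a walk started
    inside the region can never leave it.
    """
    label = label if isinstance(label, TrieneLabel) else TrieneLabel.from_string(label)
    bounds = {"+c": (0.0, 90.0), "+t": (90.0, 180.0), "-c": (-90.0, 0.0), "-t": (-180.0, -90.0)}
    (lo1, hi1), (lo2, hi2) = bounds[label.q1], bounds[label.q2]

    def potential(phi1, phi2):
        phi1 = np.asarray(phi1, float)
        phi2 = np.asarray(phi2, float)
        inside = (phi1 >= lo1) & (phi1 < hi1) & (phi2 >= lo2) & (phi2 < hi2)
        return np.where(inside, depth, np.inf)

    return potential


def _grid_potential(grid: PESGrid):
    """Nearest-grid-point lookup of a PESGrid as a callable potential."""

    def potential(phi1, phi2):
        i = np.argmin(np.abs(np.subtract.outer(np.atleast_1d(phi1), grid.phi1)), axis=-1)
        j = np.argmin(np.abs(np.subtract.outer(np.atleast_1d(phi2), grid.phi2)), axis=-1)
        out = grid.values[i, j]
        return out if np.ndim(phi1) else float(out[0])

    return potential


def make_torsion_trajectory(
    potential,
    T: float = BODY_TEMPERATURE_K,
    n_steps: int = 10000,
    step_size: float = 15.0,
    seed: int | np.random.Generator = 0,
    start: tuple[float, float] | None = None,
    source: str = "synthetic",
    constants: PhysicalConstants = CODATA2018,
) -> TorsionTrajectory:
    """Metropolis random walk on a periodic (phi1, phi2) potential.

    ``potential`` is a callable (degrees -> kcal/mol; may return inf for
    walls) or a :class:`PESGrid`.  The emitted angle series is the ground
    truth for trajectory round-trip tests; with confinement walls the walk
    provably never leaves the allowed region (infinite-energy moves are
    always rejected).
    """
    if T <= 0 or n_steps < 1:
        raise ValueError("positive temperature and step count required")
    if isinstance(potential, PESGrid):
        potential = _grid_potential(potential)
    rng = _rng(seed)
    if start is None:
        start = (-45.0, -45.0)
    p1, p2 = float(start[0]), float(start[1])
    e_here = float(potential(p1, p2))
    if not np.isfinite(e_here):
        raise ValueError("start point lies inside an infinite-wall region")
    kT = constants.thermal_energy(T)
    out1 = np.empty(n_steps)
    out2 = np.empty(n_steps)
    steps = rng.uniform(-step_size, step_size, (n_steps, 2))
    accept_u = rng.uniform(0.0, 1.0, n_steps)
    for i in range(n_steps):
        q1 = (p1 + steps[i, 0] + 180.0) % 360.0 - 180.0
        q2 = (p2 + steps[i, 1] + 180.0) % 360.0 - 180.0
        q1 = 180.0 if q1 == -180.0 else q1
        q2 = 180.0 if q2 == -180.0 else q2
        e_new = float(potential(q1, q2))
        if np.isfinite(e_new) and (
            e_new <= e_here or accept_u[i] < math.exp(-(e_new - e_here) / kT)
        ):
            p1, p2, e_here = q1, q2, e_new
        out1[i] = p1
        out2[i] = p2
    return TorsionTrajectory(out1, out2, source=source)


def make_pes_grid(
    barrier_height: float,
    basin_labels: tuple[str, str] = ("-c-c", "+c+c"),
    grid_spacing: float = 5.0,
    basin_radius: float = 40.0,
) -> PESGrid:
    """Periodic double-basin surface with an analytic minimax barrier.

    Two parabolic basins of radius ``basin_radius`` (degrees) sit at the
    centres of the two quadrant pairs, surrounded by a plateau at
    ``barrier_height``; the minimax barrier between the basins is exactly
    ``barrier_height``.  Basins must not overlap (periodically).
    """
    if barrier_height < 0:
        raise ValueError("barrier height must be non-negative")
    centers = []
    bounds = {"+c": 45.0, "+t": 135.0, "-c": -45.0, "-t": -135.0}
    for name in basin_labels:
        lab = TrieneLabel.from_string(name)
        centers.append((bounds[lab.q1], bounds[lab.q2]))
    if grid_spacing > basin_radius:
        raise ValueError("grid spacing too coarse to resolve the basins")

    def periodic_d2(phi1, phi2, center):
        d1 = (phi1 - center[0] + 180.0) % 360.0 - 180.0
        d2 = (phi2 - center[1] + 180.0) % 360.0 - 180.0
        return d1**2 + d2**2

    def surface(phi1, phi2):
        d2 = np.minimum(
            periodic_d2(phi1, phi2, centers[0]), periodic_d2(phi1, phi2, centers[1])
        )
        return barrier_height * np.minimum(1.0, d2 / basin_radius**2)

    return PESGrid.from_function(surface, spacing=grid_spacing)


# ---------------------------------------------------------------------------
# end-to-end synthetic catalysis study


@dataclass
class CatalysisStudy:
    """A complete synthetic free-vs-encapsulated study with ground truth.

    ``truth`` stores the planted/reference values of every quantity the
    pipeline recomputes: partition functions, rate constants, phi and its
    five factors — all produced by the generator's own independent
    thermochemistry routine.
    """

    free_reactant: ConformerEnsemble
    free_ts: ConformerEnsemble
    enc_reactant: HostGuestSystem
    enc_ts: HostGuestSystem
    V0_free: float
    V0_enc: float
    gamma_free: tuple[float, float]  # (gamma_cvt, kappa)
    gamma_enc: tuple[float, float]
    T: float
    scale: float
    torsions: TorsionDefinition
    truth: dict


def make_catalysis_study(
    seed: int = 0,
    T: float = BODY_TEMPERATURE_K,
    scale: float = 1.0,
    coupling: float = 30.0,
    stiffen: tuple[tuple[float, float], ...] = ((24.0, 42.0), (31.0, 54.0), (46.0, 64.0)),
    constants: PhysicalConstants = CODATA2018,
) -> CatalysisStudy:
    """Synthetic emulation of the free-vs-encapsulated rate comparison.

    The free reactant ensemble spreads over reactive and non-reactive
    triene arrangements (the most stable conformer being non-reactive, as
    in the real previtamin); encapsulation keeps only the -c-c conformers
    and stiffens the guest's three lowest frequencies following the
    reported gas-phase shifts 24->42, 31->54 and 46->64 cm^-1, which
    pushes the reactant-side guest factor above 1 (an entropic speed-up of
    order a few).  The exact planted values of every derived quantity are
    stored in ``truth``.
    """
    rng = _rng(seed)
    high = np.array([95.0, 160.0, 300.0, 520.0, 780.0, 1050.0, 1320.0, 1580.0, 2900.0])
    soft_low = np.array([s for s, _ in stiffen])
    stiff_low = np.array([s for _, s in stiffen])
    reactant_spectrum = np.concatenate([soft_low, high])  # 12 modes: 6 atoms
    ts_spectrum = np.concatenate([[-1250.0], soft_low * 1.6, high[:-1]])
    free_r_spec = EnsembleSpec(
        angles=[(123.0, -48.0), (54.0, 43.0), (-57.0, -46.0), (-150.0, 120.0)],
        energies=[0.0, 1.58, 1.67, 2.4],
        spectra=[reactant_spectrum * float(f) for f in (1.0, 1.02, 0.98, 1.05)],
        role="reactant",
        seed=int(rng.integers(2**31)),
        solvent="n-hexane",
    )
    free_ts_spec = EnsembleSpec(
        angles=[(52.0, 40.0), (-55.0, -44.0)],
        energies=[0.0, 1.54],
        spectra=[ts_spectrum, ts_spectrum * 0.99],
        role="transition_state",
        seed=int(rng.integers(2**31)),
        solvent="n-hexane",
    )
    free_reactant = make_ensemble(free_r_spec)
    free_ts = make_ensemble(free_ts_spec)
    V0_free, V0_enc = 28.07, 27.63
    # absolute energy bookkeeping: reactant minimum defines the zero
    free_ts.reference_energy = V0_free

    # encapsulated: only the -c-c guest conformer, low modes stiffened
    enc_guest_r = np.concatenate([stiff_low, high])
    enc_guest_ts = np.concatenate([[-1250.0], stiff_low * 1.05, high[:-1] * 1.01])
    host = np.linspace(40.0, 900.0, 3 * 8 - 6)
    enc_reactant = make_host_guest(
        HostGuestSpec(
            guest_spectrum=enc_guest_r,
            host_spectrum=host,
            coupling=coupling,
            seed=int(rng.integers(2**31)),
        )
    )
    enc_ts = make_host_guest(
        HostGuestSpec(
            guest_spectrum=enc_guest_ts,
            host_spectrum=host * 1.005,
            coupling=coupling,
            seed=int(rng.integers(2**31)),
        )
    )
    gamma_free = (0.95, 1.30)
    gamma_enc = (0.92, 1.55)

    # ---- generator-side ground truth (independent thermochemistry) ----
    kT = constants.thermal_energy(T)
    Q_f_R = _reference_ms_q(free_reactant, T, scale, constants=constants)
    Q_f_TS = _reference_ms_q(free_ts, T, scale, constants=constants)
    sub = {}
    for tag, system in (("R", enc_reactant), ("TS", enc_ts)):
        c = system.conformer
        bt = system.blocks_truth
        q_full, _ = _reference_q_rovib(c.hessian, c.geometry, c.masses, T, scale)
        q_g, _ = _reference_q_rovib(
            bt["F_guest"], bt["guest_geometry"], bt["guest_masses"], T, scale
        )
        q_h, _ = _reference_q_rovib(
            bt["F_host"], bt["host_geometry"], bt["host_masses"], T, scale
        )
        sub[tag] = SubsystemQs(q_full, q_g, q_h)
    prefactor = constants.kB_SI * T / constants.h_SI
    k_f = (
        gamma_free[0]
        * gamma_free[1]
        * prefactor
        * Q_f_TS
        / Q_f_R
        * math.exp(-V0_free / kT)
    )
    k_e = (
        gamma_enc[0]
        * gamma_enc[1]
        * prefactor
        * sub["TS"].Q_full
        / sub["R"].Q_full
        * math.exp(-V0_enc / kT)
    )
    phi = k_e / k_f
    phi_gamma = (gamma_enc[0] * gamma_enc[1]) / (gamma_free[0] * gamma_free[1])
    phi_V0 = math.exp(-(V0_enc - V0_free) / kT)
    phi_guest = (sub["TS"].Q_guest / Q_f_TS) / (sub["R"].Q_guest / Q_f_R)
    phi_host = sub["TS"].Q_host / sub["R"].Q_host
    phi_coup = phi / (phi_gamma * phi_V0 * phi_guest * phi_host)
    truth = {
        "Q_f_R": Q_f_R,
        "Q_f_TS": Q_f_TS,
        "subsystems": sub,
        "k_free": k_f,
        "k_enc": k_e,
        "phi": phi,
        "phi_gamma": phi_gamma,
        "phi_V0": phi_V0,
        "phi_guest": phi_guest,
        "phi_host": phi_host,
        "phi_coup": phi_coup,
        "f_coup_R": sub["R"].f_coup,
        "f_coup_TS": sub["TS"].f_coup,
    }
    return CatalysisStudy(
        free_reactant=free_reactant,
        free_ts=free_ts,
        enc_reactant=enc_reactant,
        enc_ts=enc_ts,
        V0_free=V0_free,
        V0_enc=V0_enc,
        gamma_free=gamma_free,
        gamma_enc=gamma_enc,
        T=T,
        scale=scale,
        torsions=DEFAULT_TORSIONS,
        truth=truth,
    )
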