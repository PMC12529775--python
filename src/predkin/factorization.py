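"""Host-guest factorization of the encapsulated partition function.

The Hessian of the encapsulated system splits into four blocks

    F_[e] = [[F_guest, F_coup], [F_coup^T, F_host]],

guest = the previtamin, host = the cyclodextrin dimer.  Diagonalizing each
diagonal block at its embedded sub-geometry gives subsystem partition
functions, and the full partition function factorizes as

    Q_[e] = Q_guest_[e] * Q_host_[e] * f_coup,

where f_coup is the closing residual carrying the guest-host coupling
(including the six residual intermolecular modes).  The catalytic ratio
then decomposes exactly into five factors

    phi = phi_gamma * phi_V0 * phi_guest * phi_host * phi_coup,

with phi_guest = (Q_guest_[e]/Q_[f])_TS / (Q_guest_[e]/Q_[f])_R comparing
the embedded guest against the free molecule, phi_host the analogous
host-only ratio, and phi_coup closing the product identity.

Convention: subsystem partition functions project the subsystem's *own*
six external modes, so the embedded guest is compared like-with-like
against the free molecule; whatever curvature those displaced external
modes carry lands in f_coup, which keeps the residual interpretable as
intermolecular motion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import CODATA2018, PhysicalConstants
from .errors import PartitionError, StationaryPointError
from .kinetics import RateResult, catalytic_ratio
from .partition import (
    FrequencySet,
    external_mode_basis,
    n_external_modes,
    q_rot,
    q_vib,
)

__all__ = [
    "HostGuestPartition",
    "HessianBlocks",
    "SubsystemQ",
    "FactorDecomposition",
    "GuestLadder",
    "split_hessian",
    "assemble_hessian",
    "subsystem_partition_function",
    "coupling_factor",
    "decompose_catalytic_ratio",
    "phi_guest_ladder",
]

#: Projected modes with |wavenumber| below this floor (cm^-1) are treated
#: as numerically-zero external remnants and dropped (with their count
#: recorded).  An uncoupled guest leaves exactly six such modes in the
#: full system.
MODE_FLOOR_CM = 0.1


@dataclass(frozen=True)
class HostGuestPartition:
    """Disjoint guest/host atom index sets covering the whole system."""

    guest_atoms: tuple[int, ...]
    host_atoms: tuple[int, ...]

    def __post_init__(self) -> None:
        g, h = set(self.guest_atoms), set(self.host_atoms)
        if not g or not h:
            raise PartitionError("guest and host atom sets must be non-empty")
        if g & h:
            raise PartitionError(f"overlapping guest/host atoms: {sorted(g & h)}")
        n = len(g) + len(h)
        if g | h != set(range(n)):
            raise PartitionError(
                "guest and host atom sets must cover atoms 0..N-1 exactly"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.guest_atoms) + len(self.host_atoms)

    def cartesian_indices(self, atoms: tuple[int, ...]) -> np.ndarray:
        return np.concatenate([[3 * a, 3 * a + 1, 3 * a + 2] for a in atoms])

    def swapped(self) -> "HostGuestPartition":
        return HostGuestPartition(self.host_atoms, self.guest_atoms)


@dataclass
class HessianBlocks:
    """The four blocks of a host-guest Hessian (guest, host, coupling)."""

    F_guest: np.ndarray
    F_host: np.ndarray
    F_coup: np.ndarray  # 3Ng x 3Nh
    partition: HostGuestPartition

    def reassemble(self) -> np.ndarray:
        return assemble_hessian(self)


def split_hessian(F_e: np.ndarray, partition: HostGuestPartition) -> HessianBlocks:
    """Slice a full Hessian into guest/host/coupling blocks (lossless)."""
    F_e = np.asarray(F_e, dtype=float)
    n = partition.n_atoms
    if F_e.shape != (3 * n, 3 * n):
        raise PartitionError(
            f"hessian shape {F_e.shape} inconsistent with {n}-atom partition"
        )
    scale = np.abs(F_e).max()
    if scale > 0 and np.abs(F_e - F_e.T).max() > 1e-8 * scale:
        raise PartitionError("hessian is not symmetric")
    gi = partition.cartesian_indices(partition.guest_atoms)
    hi = partition.cartesian_indices(partition.host_atoms)
    return HessianBlocks(
        F_guest=F_e[np.ix_(gi, gi)].copy(),
        F_host=F_e[np.ix_(hi, hi)].copy(),
        F_coup=F_e[np.ix_(gi, hi)].copy(),
        partition=partition,
    )


def assemble_hessian(blocks: HessianBlocks) -> np.ndarray:
    """Inverse of split_hessian; bit-exact round trip."""
    p = blocks.partition
    n = p.n_atoms
    gi = p.cartesian_indices(p.guest_atoms)
    hi = p.cartesian_indices(p.host_atoms)
    F = np.zeros((3 * n, 3 * n))
    F[np.ix_(gi, gi)] = blocks.F_guest
    F[np.ix_(hi, hi)] = blocks.F_host
    F[np.ix_(gi, hi)] = blocks.F_coup
    F[np.ix_(hi, gi)] = blocks.F_coup.T
    return F


@dataclass
class SubsystemQ:
    """Partition function of a (sub)system treated as a molecule in place."""

    Q: float  # q_vib or q_rot*q_vib depending on include_rotation
    q_vib: float
    q_rot: float
    frequencies: FrequencySet
    n_dropped: int  # sub-floor modes removed before the product
    include_rotation: bool

    @property
    def n_modes(self) -> int:
        return len(self.frequencies.real_wavenumbers) + self.frequencies.n_imag


def subsystem_partition_function(
    block: np.ndarray,
    sub_geometry: np.ndarray,
    sub_masses: np.ndarray,
    T: float,
    scale_factor: float = 1.0,
    n_imag_expected: int = 0,
    include_rotation: bool = True,
    symmetry_number: int = 1,
    mode_floor_cm: float = MODE_FLOOR_CM,
    constants: PhysicalConstants = CODATA2018,
) -> SubsystemQ:
    """Rovibrational partition function of a Hessian block in place.

    The block is treated as the Hessian of a molecule frozen at its
    embedded geometry: the subsystem's own 6 (5 if linear) external modes
    are projected out, the remaining spectrum is scaled, and q_rot * q_vib
    is formed.  Residual modes below ``mode_floor_cm`` (numerically-zero
    leftovers, e.g. the intermolecular modes of an uncoupled complex) are
    dropped and counted.  For a transition-state subsystem containing the
    transferred atom one imaginary mode is tolerated per
    ``n_imag_expected``.
    """
    from .partition import project_and_mass_weight  # local import, no cycle

    sub_masses = np.asarray(sub_masses, float)
    if len(sub_masses) < 2:
        raise PartitionError("a subsystem needs at least 2 atoms")
    n_project = n_external_modes(sub_geometry, sub_masses)
    projected = project_and_mass_weight(block, sub_masses, sub_geometry, n_project)
    eigvals = np.linalg.eigvalsh(projected)
    order = np.argsort(np.abs(eigvals))
    internal = eigvals[order[n_project:]]
    omega = np.sqrt(np.abs(internal) * constants.hessian_eigval_to_s2)
    wn = np.sign(internal) * omega / (2.0 * math.pi * constants.c_cm) * scale_factor
    kept = wn[np.abs(wn) >= mode_floor_cm]
    n_dropped = len(wn) - len(kept)
    real = kept[kept > 0]
    imag = -kept[kept <= 0]
    if len(imag) != n_imag_expected:
        raise StationaryPointError(
            f"subsystem has {len(imag)} imaginary modes, expected {n_imag_expected}"
        )
    freqs = FrequencySet(real, imag if len(imag) else np.empty(0), scale_factor)
    qv = q_vib(freqs, T, constants)
    qr = (
        q_rot(sub_geometry, sub_masses, symmetry_number, T, constants)
        if include_rotation
        else 1.0
    )
    return SubsystemQ(
        Q=qr * qv,
        q_vib=qv,
        q_rot=qr,
        frequencies=freqs,
        n_dropped=n_dropped,
        include_rotation=include_rotation,
    )


def coupling_factor(Q_full_e: float, Q_guest_e: float, Q_host_e: float) -> float:
    """f_coup = Q_[e] / (Q_guest_[e] * Q_host_[e]), the Eq-5 residual."""
    if Q_full_e <= 0 or Q_guest_e <= 0 or Q_host_e <= 0:
        raise ValueError("partition functions must be positive")
    return Q_full_e / (Q_guest_e * Q_host_e)


@dataclass
class SubsystemQs:
    """The Eq-5 ingredients for one stationary point of the encapsulated
    system: full-system, guest-block and host-block partition functions."""

    Q_full: float
    Q_guest: float
    Q_host: float

    @property
    def f_coup(self) -> float:
        return coupling_factor(self.Q_full, self.Q_guest, self.Q_host)


@dataclass
class FactorDecomposition:
    """phi and its five multiplicative factors.

    phi_coup is computed as the closing residual phi / (product of the
    other four), mirroring how f_coup itself is defined from Q_[e]; the
    product identity is therefore exact by construction and asserted.
    """

    phi: float
    phi_gamma: float
    phi_V0: float
    phi_guest: float
    phi_host: float
    phi_coup: float
    f_coup_R: float
    f_coup_TS: float
    T: float

    def __post_init__(self) -> None:
        product = (
            self.phi_gamma * self.phi_V0 * self.phi_guest * self.phi_host * self.phi_coup
        )
        if not math.isclose(product, self.phi, rel_tol=1e-9):
            raise ValueError(
                f"factor product {product} != phi {self.phi} (inconsistent inputs)"
            )


def decompose_catalytic_ratio(
    rates_free: RateResult,
    rates_enc: RateResult,
    blocks_R: SubsystemQs,
    blocks_TS: SubsystemQs,
    constants: PhysicalConstants = CODATA2018,
) -> FactorDecomposition:
    """Split phi = k_[e]/k_[f] into its five multiplicative factors.

    * phi_gamma: ratio of total transmission coefficients gamma_[e]/gamma_[f]
    * phi_V0:    exp(-(V0_[e] - V0_[f]) / kB T)
    * phi_guest: (Q_guest_[e]/Q_[f])_TS / (Q_guest_[e]/Q_[f])_R
    * phi_host:  (Q_host_[e])_TS / (Q_host_[e])_R
    * phi_coup:  the closing residual (equals f_coup_TS/f_coup_R when the
      encapsulated rate was computed from the full-system Qs)
    """
    if abs(rates_free.T - rates_enc.T) > 1e-9:
        raise ValueError("free and encapsulated rates at different temperatures")
    T = rates_free.T
    phi = catalytic_ratio(rates_enc.k, rates_free.k)
    g_free = rates_free.transmission.gamma_total if rates_free.transmission else 1.0
    g_enc = rates_enc.transmission.gamma_total if rates_enc.transmission else 1.0
    phi_gamma = g_enc / g_free
    phi_V0 = math.exp(-(rates_enc.V0 - rates_free.V0) / constants.thermal_energy(T))

    def _q(value) -> float:
        return value.Q if hasattr(value, "Q") else float(value)

    qf_R = _q(rates_free.Q_R)
    qf_TS = _q(rates_free.Q_TS)
    phi_guest = (blocks_TS.Q_guest / qf_TS) / (blocks_R.Q_guest / qf_R)
    phi_host = blocks_TS.Q_host / blocks_R.Q_host
    phi_coup = phi / (phi_gamma * phi_V0 * phi_guest * phi_host)
    return FactorDecomposition(
        phi=phi,
        phi_gamma=phi_gamma,
        phi_V0=phi_V0,
        phi_guest=phi_guest,
        phi_host=phi_host,
        phi_coup=phi_coup,
        f_coup_R=blocks_R.f_coup,
        f_coup_TS=blocks_TS.f_coup,
        T=T,
    )


#: Reaction names of the phi_guest ladder, in thermodynamic-cycle order:
#: free/n-hexane all conformers -> free/n-hexane -c-c only -> free/gas
#: -c-c -> encapsulated/gas -c-c -> encapsulated/water -c-c.
LADDER_REACTIONS = ("f_nh", "f_nh-", "f_g-", "e_g-", "e_w-")


@dataclass
class GuestLadder:
    """phi_guest split into its three physical sub-factors.

    (i)  conformational restriction: all conformers vs. -c-c only,
    (ii) encapsulation stiffening of the guest's low-frequency modes,
    (iii) solvent change (n-hexane -> gas -> water legs combined).
    The product of the three equals the end-to-end phi_guest exactly.
    """

    restriction: float
    stiffening: float
    solvent: float

    @property
    def total(self) -> float:
        return self.restriction * self.stiffening * self.solvent


def phi_guest_ladder(
    q_sets: dict[str, tuple[float, float]],
    conformer_ids: dict[str, tuple[frozenset, frozenset]] | None = None,
) -> GuestLadder:
    """Decompose phi_guest through the hypothetical intermediate reactions.

    ``q_sets`` maps each reaction name in ``LADDER_REACTIONS`` to its
    (Q_reactant, Q_TS) pair at a common temperature.  When
    ``conformer_ids`` is given (same keys, (reactant ids, TS ids)), the
    restricted reactions (names ending in ``-``) are checked to be true
    subsets of their parent reaction's conformers.
    """
    missing = [name for name in LADDER_REACTIONS if name not in q_sets]
    if missing:
        raise ValueError(f"missing ladder reactions: {missing}")
    for name, (q_r, q_ts) in q_sets.items():
        if q_r <= 0 or q_ts <= 0:
            raise ValueError(f"non-positive partition function for {name!r}")
    if conformer_ids is not None:
        full_r, full_ts = conformer_ids["f_nh"]
        sub_r, sub_ts = conformer_ids["f_nh-"]
        if not (sub_r <= full_r and sub_ts <= full_ts):
            raise ValueError(
                "restricted (-c-c) conformer sets must be subsets of the "
                "unrestricted reaction's sets"
            )

    def step(frm: str, to: str) -> float:
        (qr_a, qts_a), (qr_b, qts_b) = q_sets[frm], q_sets[to]
        return (qts_b / qts_a) / (qr_b / qr_a)

    restriction = step("f_nh", "f_nh-")
    stiffening = step("f_g-", "e_g-")
    solvent = step("f_nh-", "f_g-") * step("e_g-", "e_w-")
    ladder = GuestLadder(restriction, stiffening, solvent)
    end_to_end = step("f_nh", "e_w-")
    if not math.isclose(ladder.total, end_to_end, rel_tol=1e-9):
        raise AssertionError("ladder product does not telescope (numerical bug)")
    return ladder
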