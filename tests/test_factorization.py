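"""Host-guest Hessian blocks, f_coup and the five-factor decomposition."""

import math

import numpy as np
import pytest

from predkin.conformers import ConformerEnsemble
from predkin.constants import BODY_TEMPERATURE_K
from predkin.errors import PartitionError
from predkin.factorization import (
    HostGuestPartition,
    SubsystemQs,
    assemble_hessian,
    coupling_factor,
    decompose_catalytic_ratio,
    phi_guest_ladder,
    split_hessian,
    subsystem_partition_function,
)
from predkin.kinetics import RateResult, TransmissionCoefficients, rate_from_partition_functions
from predkin.partition import ms_partition
from predkin.synthetic import HostGuestSpec, make_host_guest

T = BODY_TEMPERATURE_K


def _block_diag_system(seed=5, coupling=0.0):
    return make_host_guest(
        HostGuestSpec(
            guest_spectrum=np.linspace(50.0, 1500.0, 12),
            host_spectrum=np.linspace(40.0, 900.0, 18),
            coupling=coupling,
            seed=seed,
        )
    )


class TestSplitHessian:
    def test_two_atom_round_trip(self, rng):
        raw = rng.normal(size=(6, 6))
        F = 0.5 * (raw + raw.T)
        part = HostGuestPartition((0,), (1,))
        blocks = split_hessian(F, part)
        assert blocks.F_guest.shape == (3, 3)
        assert blocks.F_host.shape == (3, 3)
        assert np.array_equal(assemble_hessian(blocks), F)

    def test_block_diagonal_gives_zero_coupling(self):
        system = _block_diag_system()
        blocks = split_hessian(system.conformer.hessian, system.partition)
        assert np.all(blocks.F_coup == 0.0)

    def test_interleaved_partition_matches_elementwise_gather(self, rng):
        """Guest atoms scattered through the atom order: blocks must match a
        brute-force element-by-element index gather."""
        n = 5
        raw = rng.normal(size=(3 * n, 3 * n))
        F = 0.5 * (raw + raw.T)
        part = HostGuestPartition((0, 2, 4), (1, 3))
        blocks = split_hessian(F, part)
        for bi, a in enumerate(part.guest_atoms):
            for bj, b in enumerate(part.guest_atoms):
                for x in range(3):
                    for y in range(3):
                        assert blocks.F_guest[3 * bi + x, 3 * bj + y] == F[3 * a + x, 3 * b + y]
        for bi, a in enumerate(part.guest_atoms):
            for bj, b in enumerate(part.host_atoms):
                for x in range(3):
                    for y in range(3):
                        assert blocks.F_coup[3 * bi + x, 3 * bj + y] == F[3 * a + x, 3 * b + y]
        assert np.array_equal(assemble_hessian(blocks), F)

    def test_overlapping_partition_rejected(self):
        with pytest.raises(PartitionError):
            HostGuestPartition((0, 1), (1, 2))

    def test_incomplete_partition_rejected(self):
        with pytest.raises(PartitionError):
            HostGuestPartition((0,), (2,))


class TestSubsystemQ:
    def test_full_system_partition_is_degenerate_case(self):
        """Treating the whole system as the 'subsystem' reproduces the
        plain rovibrational partition function."""
        system = _block_diag_system(coupling=25.0)
        c = system.conformer
        sub = subsystem_partition_function(c.hessian, c.geometry, c.masses, T)
        ens = ConformerEnsemble([c], "reactant", "encapsulated")
        full = ms_partition(ens, T, scale_factor=1.0)
        assert sub.Q == pytest.approx(full.Q, rel=1e-10)

    def test_block_diagonal_separability(self):
        """For an uncoupled complex the product of subsystem partition
        functions equals the full vibrational partition function."""
        system = _block_diag_system()
        c = system.conformer
        bt = system.blocks_truth
        kwargs = dict(T=T, include_rotation=False)
        q_full = subsystem_partition_function(c.hessian, c.geometry, c.masses, **kwargs)
        q_g = subsystem_partition_function(
            bt["F_guest"], bt["guest_geometry"], bt["guest_masses"], **kwargs
        )
        q_h = subsystem_partition_function(
            bt["F_host"], bt["host_geometry"], bt["host_masses"], **kwargs
        )
        assert q_full.n_dropped == 6  # residual intermolecular zeros
        assert coupling_factor(q_full.Q, q_g.Q, q_h.Q) == pytest.approx(1.0, rel=1e-9)

    def test_coupled_subsystem_matches_direct_diagonalization(self):
        """Subsystem frequencies from a coupled complex equal a brute-force
        eigendecomposition of the isolated diagonal block."""
        import scipy.linalg

        from predkin.constants import CODATA2018 as C
        from predkin.partition import external_mode_basis

        system = _block_diag_system(coupling=30.0)
        blocks = split_hessian(system.conformer.hessian, system.partition)
        bt = system.blocks_truth
        sub = subsystem_partition_function(
            blocks.F_guest, bt["guest_geometry"], bt["guest_masses"], T
        )
        sqm = np.repeat(np.sqrt(bt["guest_masses"]), 3)
        h_mw = blocks.F_guest / np.outer(sqm, sqm)
        basis = external_mode_basis(bt["guest_geometry"], bt["guest_masses"])
        proj = np.eye(len(sqm)) - basis @ basis.T
        eig = np.sort(scipy.linalg.eigvalsh(proj @ h_mw @ proj))
        internal = eig[np.argsort(np.abs(eig))[6:]]
        oracle = np.sort(
            np.sqrt(np.abs(internal) * C.hessian_eigval_to_s2) / (2 * math.pi * C.c_cm)
        )
        assert np.allclose(np.sort(sub.frequencies.real_wavenumbers), oracle, rtol=1e-9)

    def test_mode_count_accounting(self):
        """Full system: 3N-6 internal modes; guest + host blocks: 3N-12;
        the 6 residual intermolecular modes live only in f_coup."""
        system = _block_diag_system(coupling=30.0)
        c = system.conformer
        bt = system.blocks_truth
        blocks = split_hessian(c.hessian, system.partition)
        n = c.n_atoms
        q_full = subsystem_partition_function(c.hessian, c.geometry, c.masses, T)
        q_g = subsystem_partition_function(
            blocks.F_guest, bt["guest_geometry"], bt["guest_masses"], T
        )
        q_h = subsystem_partition_function(
            blocks.F_host, bt["host_geometry"], bt["host_masses"], T
        )
        assert q_full.n_modes + q_full.n_dropped == 3 * n - 6
        assert q_g.n_modes + q_h.n_modes == 3 * n - 12
        assert (q_full.n_modes + q_full.n_dropped) - (q_g.n_modes + q_h.n_modes) == 6


class TestCouplingFactor:
    def test_uncoupled_is_one(self):
        system = _block_diag_system()
        bt = system.blocks_truth
        c = system.conformer
        kwargs = dict(T=T, include_rotation=False)
        q_full = subsystem_partition_function(c.hessian, c.geometry, c.masses, **kwargs)
        q_g = subsystem_partition_function(
            bt["F_guest"], bt["guest_geometry"], bt["guest_masses"], **kwargs
        )
        q_h = subsystem_partition_function(
            bt["F_host"], bt["host_geometry"], bt["host_masses"], **kwargs
        )
        assert q_full.Q / (q_g.Q * q_h.Q) == pytest.approx(1.0, rel=1e-9)

    def test_algebraic_identity(self):
        f = coupling_factor(12.0, 3.0, 2.0)
        assert f * 3.0 * 2.0 == pytest.approx(12.0, rel=1e-15)

    def test_planted_coupling_matches_eigenvalue_oracle(self):
        """f_coup from the package equals the value assembled from
        independently diagonalized full vs. block spectra."""
        from predkin.synthetic import _reference_q_rovib

        system = _block_diag_system(coupling=30.0)
        c = system.conformer
        bt = system.blocks_truth
        blocks = split_hessian(c.hessian, system.partition)
        q_full = subsystem_partition_function(c.hessian, c.geometry, c.masses, T)
        q_g = subsystem_partition_function(
            blocks.F_guest, bt["guest_geometry"], bt["guest_masses"], T
        )
        q_h = subsystem_partition_function(
            blocks.F_host, bt["host_geometry"], bt["host_masses"], T
        )
        got = coupling_factor(q_full.Q, q_g.Q, q_h.Q)
        ref_full, _ = _reference_q_rovib(c.hessian, c.geometry, c.masses, T)
        ref_g, _ = _reference_q_rovib(bt["F_guest"], bt["guest_geometry"], bt["guest_masses"], T)
        ref_h, _ = _reference_q_rovib(bt["F_host"], bt["host_geometry"], bt["host_masses"], T)
        assert got == pytest.approx(ref_full / (ref_g * ref_h), rel=1e-9)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            coupling_factor(1.0, 0.0, 2.0)


def _study_rates_and_blocks(study):
    QfR = ms_partition(study.free_reactant, study.T, study.scale)
    QfTS = ms_partition(study.free_ts, study.T, study.scale)
    k_free = rate_from_partition_functions(
        QfR, QfTS, study.V0_free, TransmissionCoefficients(*study.gamma_free)
    )
    encR = ConformerEnsemble(
        [study.enc_reactant.conformer], "reactant", "encapsulated", "water"
    )
    encTS = ConformerEnsemble(
        [study.enc_ts.conformer], "transition_state", "encapsulated", "water"
    )
    k_enc = rate_from_partition_functions(
        ms_partition(encR, study.T, study.scale),
        ms_partition(encTS, study.T, study.scale),
        study.V0_enc,
        TransmissionCoefficients(*study.gamma_enc),
    )
    subs = {}
    for tag, system in (("R", study.enc_reactant), ("TS", study.enc_ts)):
        blocks = split_hessian(system.conformer.hessian, system.partition)
        n_imag = system.conformer.n_imag_expected
        bt = system.blocks_truth
        q_full = subsystem_partition_function(
            system.conformer.hessian, system.conformer.geometry,
            system.conformer.masses, study.T, study.scale, n_imag_expected=n_imag,
        )
        q_g = subsystem_partition_function(
            blocks.F_guest, bt["guest_geometry"], bt["guest_masses"],
            study.T, study.scale, n_imag_expected=n_imag,
        )
        q_h = subsystem_partition_function(
            blocks.F_host, bt["host_geometry"], bt["host_masses"],
            study.T, study.scale,
        )
        subs[tag] = SubsystemQs(q_full.Q, q_g.Q, q_h.Q)
    return k_free, k_enc, subs


class TestDecomposition:
    def test_identical_inputs_give_unit_factors(self, study):
        k_free, _, subs = _study_rates_and_blocks(study)
        dec = decompose_catalytic_ratio(k_free, k_free, subs["R"], subs["R"])
        # phi_guest compares the same subsystem against the same free Q
        assert dec.phi == pytest.approx(1.0, rel=1e-12)
        assert dec.phi_gamma == pytest.approx(1.0, rel=1e-12)
        assert dec.phi_V0 == pytest.approx(1.0, rel=1e-12)

    def test_phi_v0_from_smd_barriers(self, study):
        k_free, k_enc, subs = _study_rates_and_blocks(study)
        import dataclasses

        k_free_smd = dataclasses.replace(k_free, V0=27.40)
        k_enc_smd = dataclasses.replace(k_enc, V0=27.88)
        dec = decompose_catalytic_ratio(k_free_smd, k_enc_smd, subs["R"], subs["TS"])
        assert dec.phi_V0 == pytest.approx(0.46, abs=0.005)

    def test_planted_factor_recovery(self, study):
        """End-to-end: the decomposition recovers every planted factor of
        the synthetic host-guest study to 1e-9 relative."""
        k_free, k_enc, subs = _study_rates_and_blocks(study)
        dec = decompose_catalytic_ratio(k_free, k_enc, subs["R"], subs["TS"])
        truth = study.truth
        for name in ("phi", "phi_gamma", "phi_V0", "phi_guest", "phi_host",
                     "phi_coup", "f_coup_R", "f_coup_TS"):
            assert getattr(dec, name) == pytest.approx(truth[name], rel=1e-9), name

    def test_product_identity(self, study):
        k_free, k_enc, subs = _study_rates_and_blocks(study)
        dec = decompose_catalytic_ratio(k_free, k_enc, subs["R"], subs["TS"])
        product = dec.phi_gamma * dec.phi_V0 * dec.phi_guest * dec.phi_host * dec.phi_coup
        assert product == pytest.approx(dec.phi, rel=1e-9)

    def test_temperature_mismatch_rejected(self, study):
        import dataclasses

        k_free, k_enc, subs = _study_rates_and_blocks(study)
        bad = dataclasses.replace(k_enc, T=300.0)
        with pytest.raises(ValueError, match="temperature"):
            decompose_catalytic_ratio(k_free, bad, subs["R"], subs["TS"])


class TestGuestLadder:
    base = {
        "f_nh": (10.0, 4.0),
        "f_nh-": (5.0, 3.0),
        "f_g-": (6.0, 3.5),
        "e_g-": (3.0, 2.8),
        "e_w-": (2.5, 2.6),
    }

    def test_identical_reactions_give_unit_ladder(self):
        sets = {name: (7.0, 3.0) for name in self.base}
        ladder = phi_guest_ladder(sets)
        assert (ladder.restriction, ladder.stiffening, ladder.solvent) == (1.0, 1.0, 1.0)

    def test_halved_reactant_q_doubles_restriction_factor(self):
        sets = dict(self.base)
        sets["f_nh"] = (10.0, 4.0)
        sets["f_nh-"] = (5.0, 4.0)  # Q_R halved, Q_TS unchanged
        assert phi_guest_ladder(sets).restriction == pytest.approx(2.0, rel=1e-12)

    def test_ladder_telescopes_to_end_to_end(self):
        ladder = phi_guest_ladder(self.base)
        (qr_a, qts_a), (qr_b, qts_b) = self.base["f_nh"], self.base["e_w-"]
        end = (qts_b / qts_a) / (qr_b / qr_a)
        assert ladder.total == pytest.approx(end, rel=1e-12)

    def test_stiffening_raises_factor_above_one(self):
        """Raising the guest's low frequencies on encapsulation (reactant
        side) lowers Q_R[e] and pushes the stiffening factor above 1."""
        from predkin.partition import FrequencySet, q_vib

        soft = FrequencySet(np.array([24.0, 31.0, 46.0, 300.0]), np.empty(0))
        stiff = FrequencySet(np.array([42.0, 54.0, 64.0, 300.0]), np.empty(0))
        ts = FrequencySet(np.array([80.0, 90.0, 100.0, 310.0]), np.empty(0))
        sets = dict(self.base)
        sets["f_g-"] = (q_vib(soft, T), q_vib(ts, T))
        sets["e_g-"] = (q_vib(stiff, T), q_vib(ts, T) * 0.98)
        ladder = phi_guest_ladder(sets)
        assert ladder.stiffening > 1.0

    def test_subset_violation_rejected(self):
        ids = {
            "f_nh": (frozenset({"a", "b"}), frozenset({"t1"})),
            "f_nh-": (frozenset({"a", "z"}), frozenset({"t1"})),  # z not a subset
            "f_g-": (frozenset({"a"}), frozenset({"t1"})),
            "e_g-": (frozenset({"a"}), frozenset({"t1"})),
            "e_w-": (frozenset({"a"}), frozenset({"t1"})),
        }
        with pytest.raises(ValueError, match="subset"):
            phi_guest_ladder(self.base, conformer_ids=ids)

    def test_missing_reaction_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            phi_guest_ladder({"f_nh": (1.0, 1.0)})
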