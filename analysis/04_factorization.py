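#!/usr/bin/env python
"""Five-factor decomposition of the catalytic ratio on synthetic data.

Runs the complete synthetic free-vs-encapsulated study (planted conformer
ensembles, host-guest Hessians with coupling springs, stiffened guest
low-frequency modes), computes both MS-VTST rate constants, decomposes
phi = phi_gamma * phi_V0 * phi_guest * phi_host * phi_coup, and verifies
every factor against the generator's planted ground truth.  Also splits
phi_guest through the ladder of hypothetical intermediate reactions
(conformational restriction / encapsulation stiffening / solvent).

Writes results/factor_table.csv and results/phi_guest_ladder.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from predkin.conformers import ConformerEnsemble
from predkin.factorization import (
    SubsystemQs,
    decompose_catalytic_ratio,
    phi_guest_ladder,
    split_hessian,
    subsystem_partition_function,
)
from predkin.kinetics import TransmissionCoefficients, rate_from_partition_functions
from predkin.partition import ms_partition
from predkin.synthetic import make_catalysis_study

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

study = make_catalysis_study(seed=args.seed)
T, scale = study.T, study.scale

QfR = ms_partition(study.free_reactant, T, scale)
QfTS = ms_partition(study.free_ts, T, scale)
k_free = rate_from_partition_functions(
    QfR, QfTS, study.V0_free, TransmissionCoefficients(*study.gamma_free)
)
k_enc = rate_from_partition_functions(
    ms_partition(
        ConformerEnsemble([study.enc_reactant.conformer], "reactant",
                          "encapsulated", "water"), T, scale),
    ms_partition(
        ConformerEnsemble([study.enc_ts.conformer], "transition_state",
                          "encapsulated", "water"), T, scale),
    study.V0_enc,
    TransmissionCoefficients(*study.gamma_enc),
)

subs = {}
for tag, system in (("R", study.enc_reactant), ("TS", study.enc_ts)):
    blocks = split_hessian(system.conformer.hessian, system.partition)
    bt = system.blocks_truth
    n_imag = system.conformer.n_imag_expected
    subs[tag] = SubsystemQs(
        subsystem_partition_function(
            system.conformer.hessian, system.conformer.geometry,
            system.conformer.masses, T, scale, n_imag_expected=n_imag).Q,
        subsystem_partition_function(
            blocks.F_guest, bt["guest_geometry"], bt["guest_masses"],
            T, scale, n_imag_expected=n_imag).Q,
        subsystem_partition_function(
            blocks.F_host, bt["host_geometry"], bt["host_masses"], T, scale).Q,
    )

dec = decompose_catalytic_ratio(k_free, k_enc, subs["R"], subs["TS"])
names = ["phi", "phi_gamma", "phi_V0", "phi_guest", "phi_host", "phi_coup"]
table = pd.DataFrame(
    {
        "factor": names,
        "computed": [getattr(dec, n) for n in names],
        "planted": [study.truth[n] for n in names],
    }
)
table["rel_error"] = abs(table.computed - table.planted) / abs(table.planted)
table.to_csv(args.out / "factor_table.csv", index=False)
print(f"k_free = {k_free.k:.4g} s^-1,  k_enc = {k_enc.k:.4g} s^-1")
print(table.to_string(index=False))
assert table.rel_error.max() < 1e-9

# phi_guest ladder: restriction / stiffening / solvent on planted Q sets.
# Solvent legs are emulated with modest planted Q shifts; restriction uses
# the actual all-conformer vs. -c-c-only free partition functions.
from predkin.conformers import filter_by_label
from predkin.synthetic import DEFAULT_TORSIONS

QfR_cc = ms_partition(
    filter_by_label(study.free_reactant, {"-c-c"}, DEFAULT_TORSIONS), T, scale
)
QfTS_cc = ms_partition(
    filter_by_label(study.free_ts, {"-c-c"}, DEFAULT_TORSIONS), T, scale
)
q_sets = {
    "f_nh": (QfR.Q, QfTS.Q),
    "f_nh-": (QfR_cc.Q, QfTS_cc.Q),
    "f_g-": (QfR_cc.Q * 1.05, QfTS_cc.Q * 1.02),  # solvent leg (planted)
    "e_g-": (subs["R"].Q_guest * 1.05, subs["TS"].Q_guest * 1.02),
    "e_w-": (subs["R"].Q_guest, subs["TS"].Q_guest),
}
ladder = phi_guest_ladder(q_sets)
ladder_table = pd.DataFrame(
    {
        "sub_factor": ["(i) conformational restriction",
                       "(ii) encapsulation stiffening",
                       "(iii) solvent environment", "total"],
        "value": [ladder.restriction, ladder.stiffening, ladder.solvent,
                  ladder.total],
    }
)
ladder_table.to_csv(args.out / "phi_guest_ladder.csv", index=False)
print("\n" + ladder_table.to_string(index=False))
print(
    "\nEvery factor is recovered to better than 1e-9; in this synthetic "
    "study, as in the real system, the guest term dominates: restricting "
    "the reactant's conformer pool and stiffening its soft torsional modes "
    "is what accelerates the encapsulated reaction."
)
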