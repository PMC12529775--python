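#!/usr/bin/env python
"""Desk-scale kinetics from the published barriers and rate constants.

Everything here follows from numbers printed in the source study:
channel asymmetry from the 28.07 vs 29.61 kcal/mol barriers, the
gas-phase and solvent-corrected encapsulation shifts, and the catalytic
ratio from the measured and computed MS-VTST rate constants.

Writes results/rates_summary.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from predkin.constants import BODY_TEMPERATURE_K
from predkin.kinetics import barrier_factor, catalytic_ratio, ms_tst_rate

parser = argparse.ArgumentParser()
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

T = BODY_TEMPERATURE_K
rows = []

# channel asymmetry: (+) vs (-), equal partition functions
ratio_channels = ms_tst_rate(1.0, 1.0, 28.07, T) / ms_tst_rate(1.0, 1.0, 29.61, T)
rows.append(("channel_rate_ratio(+/-)", ratio_channels,
             "1.54 kcal/mol barrier gap -> ~12x faster (+) channel"))

# encapsulation shifts of the barrier
rows.append(("barrier_factor_gas", barrier_factor(27.63 - 28.07, T),
             "gas-phase dV0=-0.44 suggests ~2x speed-up"))
rows.append(("barrier_factor_smd", barrier_factor(27.88 - 27.40, T),
             "solvent-corrected dV0=+0.48 would halve the rate"))

# catalytic ratios from the printed rate constants
rows.append(("phi_theoretical", catalytic_ratio(6.07e-4, 1.01e-5),
             "computed MS-VTST rates, water/n-hexane"))
rows.append(("phi_experimental", catalytic_ratio(3.07e-4, 0.68e-5),
             "measured rates"))

table = pd.DataFrame(rows, columns=["quantity", "value", "note"])
table.to_csv(args.out / "rates_summary.csv", index=False)
print(table.to_string(index=False))
print(
    "\nThe barrier change alone cannot produce the observed ~45-60x "
    "acceleration — the solvent-corrected barriers even predict a slowdown. "
    "The catalytic effect must come from the partition-function (entropic) "
    "side, quantified in 04_factorization.py."
)
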