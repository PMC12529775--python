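#!/usr/bin/env python
"""Torsional accessibility of the triene: free vs. confined dynamics.

Runs two Metropolis walks over the (phi1, phi2) torsion space — one on a
flat potential (the free previtamin's unrestricted flexibility) and one
behind infinite walls around the reactive -c-c quadrant pair (the
cyclodextrin cavity) — and tabulates the occupancy of the sixteen triene
labels.  Writes results/torsional_occupancy.csv and the merged 2D
histograms.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from predkin.synthetic import make_torsion_trajectory, quadrant_well
from predkin.torsion import accessibility_report, histogram2d

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--steps", type=int, default=50_000)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

flat = lambda a, b: np.zeros_like(np.asarray(a, float))
walks = {
    "free": make_torsion_trajectory(
        flat, n_steps=args.steps, step_size=60.0, seed=args.seed, source="free"
    ),
    "encapsulated": make_torsion_trajectory(
        quadrant_well("-c-c"), n_steps=args.steps, seed=args.seed + 1,
        source="encapsulated",
    ),
}

rows = []
for name, walk in walks.items():
    report = accessibility_report(walk)
    hist = histogram2d(walk, 72)
    np.savetxt(args.out / f"histogram_{name}.csv", hist.counts, fmt="%d",
               delimiter=",")
    for label, occ in sorted(report.occupancy.items()):
        rows.append({"system": name, "label": label, "occupancy": occ})
    visited = sorted(str(lab) for lab in report.visited)
    print(f"{name}: visited {len(visited)} labels", end="")
    print(f" -> {visited}" if len(visited) <= 4 else "")

table = pd.DataFrame(rows)
table.to_csv(args.out / "torsional_occupancy.csv", index=False)

enc = table[table.system == "encapsulated"]
assert enc.loc[enc.label == "-c-c", "occupancy"].iloc[0] == 1.0
print(
    "\nThe confined walk never leaves -c-c (occupancy 1.0): once the cavity "
    "traps the reactive arrangement, only the (-) channel remains open.\n"
    f"Tables written to {args.out}/"
)
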