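# Methods

## The model

The thermal isomerization of previtamin D (PreD) to vitamin D is a
unimolecular [1,7]-sigmatropic hydrogen shift. Its rate at temperature T
is computed with multistructural transition-state theory:

    k_MS-TST = (kB T / h) · (Q‡^MS / Q_R^MS) · exp(−V0 / kB T)

where Q_R^MS and Q‡^MS are multistructural rovibrational partition
functions summed over all thermally accessible conformers of the reactant
and of the transition state, and V0 is the energy difference between the
most stable reactant conformer and the most stable TS conformer.
Variational recrossing and tunneling enter as multiplicative coefficients
referred to the lowest-energy TS conformer of the channel:

    k_MS-VTST = Γ0^CVT · κ0^SCT · k_MS-TST.

The catalytic effect of encapsulation is the ratio φ = k[e]/k[f] of the
encapsulated and free MS-VTST rate constants. Because the encapsulated
Hessian splits into guest (PreD), host (β-CD dimer) and coupling blocks,
its partition function factorizes as Q[e] = Q_PreD[e] · Q_β-CD[e] · f_coup,
and φ decomposes exactly into five factors

    φ = φ_γ0 · φ_V0 · φ_PreD · φ_β-CD · φ_coup

with φ_γ0 the transmission-coefficient ratio, φ_V0 = exp(−ΔV0/kB T) the
barrier term, φ_PreD = (Q_PreD[e]/Q[f])‡ / (Q_PreD[e]/Q[f])_R the guest
term, φ_β-CD = (Q_β-CD[e])‡/(Q_β-CD[e])_R the host term, and φ_coup the
closing residual.

### Assumptions

- **Local harmonic (MS-LH).** Each conformer contributes a
  harmonic-oscillator/rigid-rotor term; no torsional-anharmonicity (MS-T),
  hindered-rotor or quasi-harmonic low-frequency corrections. Every report
  records the `MS-LH` variant tag.
- **Transmission coefficients are inputs.** Γ0^CVT and κ0^SCT require
  minimum-energy-path data that cannot be reproduced from conformer sets
  alone, so they are first-class inputs. The built-in asymmetric-Eckart κ
  (parametrised by forward/reverse barriers and the saddle's imaginary
  wavenumber) is a documented approximation for when no SCT value exists.
- **Electronic degeneracy 1** (closed-shell species); symmetry numbers
  default to 1 (and stay 1 for a guest inside a host).
- **Molecule-agnostic.** Nothing assumes the actual previtamin; truncating
  the lateral chain (PreD vs. PreD3) is a data-preparation step.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| temperature | 310.15 K | human body temperature, where the reaction is studied |
| frequency scale | 0.951 | harmonic-frequency scaling for the MPWB1K/6-31+G(d,p) model chemistry behind the stationary-point data |
| zpe_in_weights | on | conformer Boltzmann weights use ZPE-corrected relative energies |
| histogram bins | 72 × 72 | 5° bins over the periodic (ϕ₁, ϕ₂) square |
| linearity threshold | 1e-8 amu·Å² | smallest principal moment below which a geometry is linear (5 external modes) |
| projection tolerance | 1e-6 | mass-weighted eigenvalue magnitude treated as a projected-out external mode |
| conditioning floor | 1 cm⁻¹ | internal frequencies below this raise a warning |
| subsystem mode floor | 0.1 cm⁻¹ | residual modes below this magnitude are dropped (and counted) in block partition functions |

Internal units: kcal/mol, Å, amu; Hessians in kcal·mol⁻¹·Å⁻² (converted
from hartree/bohr² on read); CODATA-2018 constants throughout.

## Conventions and numerical choices

- **Triene quadrants.** The four torsion classes are assigned by the
  half-open scheme +c = [0°, 90°), +t = [90°, 180°], −t = (−180°, −90°),
  −c = [−90°, 0°), which makes classification total on (−180°, 180°];
  angles landing exactly on a boundary emit a warning rather than failing
  (trajectory frames occasionally hit them). Reactive = (+c,+c) or (−c,−c).
- **Dihedral sign.** IUPAC convention (clockwise positive viewed from the
  first atom), computed with the atan2 cross-product form; collinear
  triples raise a geometry error.
- **Vibrational zero.** q_vib is ZPE-referenced per conformer
  (q → 1 as T → 0); ZPE *differences* between conformers enter the
  Boltzmann weights when `zpe_in_weights` is set. Whether the source
  barrier heights are ZPE-inclusive is not derivable from a manifest, so
  V0 is used as declared and the convention is recorded in every
  rate result (`v0_convention`).
- **Log space.** All rate expressions are evaluated as logarithms and
  exponentiated once; reports carry both k and ln k. The Eckart
  transmission probability uses the cancellation-free identity
  cosh(a+b) − cosh(a−b) = 2 sinh a sinh b so deep-tunneling probabilities
  remain accurate, and the Boltzmann average is integrated adaptively in
  two pieces split at the barrier top (relative tolerance 1e-10, checked
  to 1e-6).
- **Subsystem projection.** A Hessian block is treated as a molecule
  frozen at its embedded geometry: its *own* six (five if linear) external
  modes are projected out before diagonalization, so Q_PreD[e]/Q[f]
  compares like with like; whatever curvature the environment adds along
  those directions lands in f_coup, keeping the residual interpretable as
  intermolecular motion. Residual modes below the 0.1 cm⁻¹ floor
  (numerically-zero leftovers; exactly six of them for an uncoupled
  complex) are dropped with their count recorded.
- **f_coup and rotations.** The separability identity
  Q_full = Q_guest · Q_host holds exactly for the *vibrational* partition
  functions of a block-diagonal Hessian, but not for the rigid-rotor
  parts (the rotation of a complex is not the product of its fragments'
  rotations). Subsystem partition functions therefore expose an
  `include_rotation` switch: rovibrational values (the default) feed the
  five-factor decomposition, vibrational-only values are what the
  uncoupled-limit f_coup = 1 identity is checked on.
- **φ_coup closes the product.** φ_coup is always computed as
  φ / (φ_γ0 φ_V0 φ_PreD φ_β-CD), mirroring how f_coup itself is defined
  from Q[e]; the five-factor identity is exact by construction and
  asserted to 1e-9.
- **φ_V0 formula.** exp(−ΔV0/kB T); with the solvent-corrected barriers
  27.40 → 27.88 kcal/mol at 310.15 K this gives 0.459 (printed as 0.46).
- **Minimax barriers.** The interconversion barrier between two torsion
  regions is min over 8-connected periodic paths of the path's maximum
  energy, minus the start-basin minimum — computed by flooding grid cells
  in order of increasing energy with a union-find structure, which is
  exact for the widest-path problem. Whole energy levels are activated
  before connectivity is tested, so ties cannot truncate a path. Grids are
  normalised to min = 0 (barriers are gauge-invariant).
- **Histogram edges.** Right-open bins; +180° falls in the last bin (its
  periodic image); angles are normalised to (−180°, 180°] first.
- **Atom indexing.** 1-based in manifests and on the command line
  (chemistry convention), 0-based in the API.

## The synthetic-data generators

Every stage is testable without external data because the generators
plant their own ground truth:

- `make_conformer` builds a Hessian as U·diag(λ)·Uᵀ in mass-weighted
  coordinates, with U a seeded random orthogonal completion (QR of a
  standard-normal matrix) of the exact translation/rotation basis at the
  generated geometry — so the normal-mode engine must recover the planted
  wavenumbers exactly, and a planted negative eigenvalue must surface as
  exactly one imaginary mode.
- `make_ensemble` places the six-atom triene backbone by internal
  coordinates so the planted (ϕ₁, ϕ₂) values are exact, with planted
  relative energies and spectra.
- `make_host_guest` assembles a full Hessian from two isolated-molecule
  blocks plus isotropic springs between distinct guest–host atom pairs
  (with the compensating diagonal terms, so overall translations stay
  exact zero modes). Coupling = 0 gives an exactly block-diagonal matrix;
  coupling strong enough to corrupt the planted stationary-point type is
  rejected. Ground-truth partition functions are computed by a separate
  code path (SVD-based projector, scipy eigensolver).
- `make_catalysis_study` wires these into a complete free-vs-encapsulated
  study: a free reactant ensemble whose most stable conformer is
  non-reactive (+t−c, with the first reactive conformers 1.58 and
  1.67 kcal/mol up), barriers 28.07/27.63 kcal/mol, and an encapsulated
  −c−c-only guest whose three softest modes are stiffened following the
  reported 24→42, 31→54, 46→64 cm⁻¹ gas-phase shifts. The planted φ and
  all five factors are stored for recovery tests.
- `make_torsion_trajectory` is a Metropolis walk on a periodic (ϕ₁, ϕ₂)
  potential; infinite-energy moves are always rejected, so confinement
  walls are provably inescapable. `make_pes_grid` builds a periodic
  double-basin surface (parabolic basins of 40° radius inside a plateau)
  whose analytic minimax barrier equals the planted height.

What the generators do *not* emulate: chemically realistic cyclodextrin
geometries (fixtures are spectrally realistic, not structurally), solvent
models (solvent legs of the φ_PreD ladder are planted Q shifts),
anharmonicity, and real MD force fields. Passing tests therefore
demonstrate the correctness of the statistical machinery — projection,
partition functions, factorization algebra, barrier search — not the
accuracy of any electronic-structure method.

## Problem sizes

Synthetic guests use 6 atoms (12 internal modes), hosts 8 atoms
(18 modes), host–guest complexes 14 atoms (36 modes after projection);
torsional walks use 10³–10⁵ steps and PES grids 72×72 cells. These sizes
exercise every code path — multi-conformer sums, imaginary modes,
block splitting, periodic wrap — while keeping the full suite and the
reproduction script fast on a single CPU.

## Known limitations

- MS-LH only: no MS-T torsional anharmonicity, no hindered rotors; soft
  torsional modes are treated harmonically, which overestimates their q.
- Γ0^CVT and κ0^SCT cannot be recomputed here (no minimum-energy paths);
  the Eckart κ is a one-dimensional approximation that ignores corner
  cutting.
- The classical rigid rotor is used throughout (fine at 310 K for these
  moments of inertia).
- The minimax barrier is a lower bound on any true saddle-path barrier at
  the grid's resolution; refinement tests show the discretization error
  shrinking at least linearly with spacing.
- Absolute rate constants for the real system require the quantum-chemical
  conformer data set (geometries, energies, Hessians of 103 reactant and
  24 TS conformers per medium); with manifests of such data the same
  pipeline applies unchanged.
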