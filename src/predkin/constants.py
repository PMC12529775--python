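"""Physical constants (CODATA 2018) in the package's internal units.

Internal unit system: energies in kcal/mol, lengths in angstrom, masses in
atomic mass units (amu), temperatures in kelvin.  Hessians are stored in
kcal mol^-1 A^-2 and mass-weighted with amu, so mass-weighted eigenvalues
carry kcal mol^-1 A^-2 amu^-1 and need a single conversion factor to s^-2.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA-2018 constants with the unit conversions the package needs."""

    avogadro: float = 6.02214076e23  # mol^-1 (exact)
    kB_SI: float = 1.380649e-23  # J/K (exact)
    h_SI: float = 6.62607015e-34  # J s (exact)
    c_cm: float = 2.99792458e10  # cm/s (exact)
    amu_to_kg: float = 1.66053906660e-27
    hartree_to_kcalmol: float = 627.5094740631
    bohr_to_angstrom: float = 0.529177210903
    kcal_to_J: float = 4184.0  # thermochemical calorie (exact)

    @property
    def kB(self) -> float:
        """Boltzmann constant in kcal mol^-1 K^-1 (0.0019872 kcal/mol/K)."""
        return self.kB_SI * self.avogadro / self.kcal_to_J

    @property
    def h(self) -> float:
        """Planck constant in kcal mol^-1 s."""
        return self.h_SI * self.avogadro / self.kcal_to_J

    @property
    def wavenumber_to_kcalmol(self) -> float:
        """Energy of one photon of 1 cm^-1, in kcal/mol (h*c*NA)."""
        return self.h_SI * self.c_cm * self.avogadro / self.kcal_to_J

    @property
    def hessian_eigval_to_s2(self) -> float:
        """kcal mol^-1 A^-2 amu^-1  ->  s^-2 (angular frequency squared)."""
        return self.kcal_to_J / (self.avogadro * self.amu_to_kg * 1e-20)

    @property
    def hartree_bohr2_to_kcalmol_ang2(self) -> float:
        """Hessian unit conversion hartree/bohr^2 -> kcal mol^-1 A^-2."""
        return self.hartree_to_kcalmol / self.bohr_to_angstrom**2

    def thermal_energy(self, T: float) -> float:
        """kB*T in kcal/mol."""
        return self.kB * T


CODATA2018 = PhysicalConstants()

#: Default reaction temperature: human body temperature, 37 C.
BODY_TEMPERATURE_K = 310.15

#: Recommended harmonic-frequency scaling factor for the MPWB1K/6-31+G(d,p)
#: model chemistry used to characterise the stationary points.
DEFAULT_FREQUENCY_SCALE = 0.951
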