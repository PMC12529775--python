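"""MS-TST / MS-VTST rate constants and the catalytic ratio.

The unimolecular multistructural TST rate constant is

    k_MS-TST = (kB T / h) * (Q^MS_TS / Q^MS_R) * exp(-V0 / kB T),

with V0 the barrier height from the most stable reactant conformer to the
most stable transition-state conformer.  Variational recrossing and
tunneling enter multiplicatively,

    k_MS-VTST = Gamma0_CVT * kappa0_SCT * k_MS-TST,

where the two coefficients refer to the lowest-energy TS conformer of the
channel.  They cannot be recomputed without minimum-energy-path data, so
they are first-class inputs here; an asymmetric-Eckart tunneling
coefficient is provided as a documented stand-in when no SCT value is
available.

All exponentials are evaluated in log space; rate results carry both k and
ln k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import integrate

from .constants import BODY_TEMPERATURE_K, CODATA2018, PhysicalConstants
from .partition import PartitionFunctionResult

__all__ = [
    "TransmissionCoefficients",
    "RateResult",
    "ms_tst_rate",
    "ln_ms_tst_rate",
    "ms_vtst_rate",
    "eckart_kappa",
    "catalytic_ratio",
    "barrier_factor",
    "rate_from_partition_functions",
]


@dataclass(frozen=True)
class TransmissionCoefficients:
    """Recrossing (Gamma0_CVT) and tunneling (kappa0_SCT or Eckart) factors.

    ``provenance`` records whether the numbers were supplied as inputs
    (e.g. from an MEP-based SCT calculation) or computed by the built-in
    Eckart approximation.
    """

    gamma_cvt: float = 1.0
    kappa_tunnel: float = 1.0
    provenance: str = "input"

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma_cvt <= 1.0:
            raise ValueError(
                f"gamma_cvt must lie in (0, 1], got {self.gamma_cvt}"
            )
        if self.kappa_tunnel < 1.0 - 1e-9:
            raise ValueError(
                f"tunneling coefficient must be >= 1 for barrier tunneling, "
                f"got {self.kappa_tunnel}"
            )
        if self.provenance not in ("input", "eckart"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def gamma_total(self) -> float:
        """gamma0_CVT/SCT = Gamma0_CVT * kappa0."""
        return self.gamma_cvt * self.kappa_tunnel


@dataclass
class RateResult:
    """A rate constant with its full provenance.

    ``V0`` is the barrier height (kcal/mol) between the most stable
    reactant and TS conformers in the convention noted by
    ``v0_convention`` ("classical" or "zpe_corrected").
    """

    k: float  # s^-1
    ln_k: float
    T: float
    V0: float
    Q_R: PartitionFunctionResult | float
    Q_TS: PartitionFunctionResult | float
    transmission: TransmissionCoefficients | None = None
    channel: str = ""
    level: str = "MS-TST"
    v0_convention: str = "classical"

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("rate constant must be positive")


def ln_ms_tst_rate(
    Q_R: float,
    Q_TS: float,
    V0: float,
    T: float,
    constants: PhysicalConstants = CODATA2018,
) -> float:
    """ln of the MS-TST rate constant; safe against under/overflow."""
    if Q_R <= 0 or Q_TS <= 0:
        raise ValueError("partition functions must be positive")
    if T <= 0:
        raise ValueError("temperature must be positive")
    return (
        math.log(constants.kB_SI * T / constants.h_SI)
        + math.log(Q_TS)
        - math.log(Q_R)
        - V0 / constants.thermal_energy(T)
    )


def ms_tst_rate(
    Q_R: float,
    Q_TS: float,
    V0: float,
    T: float,
    constants: PhysicalConstants = CODATA2018,
) -> float:
    """Unimolecular MS-TST rate constant in s^-1.

    k = (kB T / h) * (Q_TS / Q_R) * exp(-V0 / kB T).
    """
    return math.exp(ln_ms_tst_rate(Q_R, Q_TS, V0, T, constants))


def rate_from_partition_functions(
    Q_R: PartitionFunctionResult,
    Q_TS: PartitionFunctionResult,
    V0: float,
    transmission: TransmissionCoefficients | None = None,
    channel: str = "",
    v0_convention: str = "classical",
    constants: PhysicalConstants = CODATA2018,
) -> RateResult:
    """Assemble a RateResult from MS partition functions and a barrier."""
    if abs(Q_R.T - Q_TS.T) > 1e-9:
        raise ValueError("reactant and TS partition functions at different T")
    ln_k = ln_ms_tst_rate(Q_R.Q, Q_TS.Q, V0, Q_R.T, constants)
    result = RateResult(
        k=math.exp(ln_k),
        ln_k=ln_k,
        T=Q_R.T,
        V0=V0,
        Q_R=Q_R,
        Q_TS=Q_TS,
        channel=channel,
        v0_convention=v0_convention,
    )
    if transmission is not None:
        result = ms_vtst_rate(result, transmission)
    return result


def ms_vtst_rate(
    k_tst: RateResult, transmission: TransmissionCoefficients
) -> RateResult:
    """Apply gamma0_CVT/SCT to an MS-TST rate: k_MS-VTST = gamma * k_MS-TST."""
    if k_tst.level != "MS-TST":
        raise ValueError("transmission coefficients apply to an MS-TST rate")
    ln_k = k_tst.ln_k + math.log(transmission.gamma_total)
    return replace(
        k_tst,
        k=math.exp(ln_k),
        ln_k=ln_k,
        transmission=transmission,
        level="MS-VTST",
    )


def _ln_sinh(x: float) -> float:
    """ln sinh x for x >= 0, stable for large x; -inf at 0."""
    if x == 0.0:
        return -math.inf
    return x - math.log(2.0) + math.log1p(-math.exp(-2.0 * x))


def _ln_eckart_transmission(xi: float, alpha1: float, alpha2: float) -> float:
    """ln of the asymmetric-Eckart transmission probability at E = xi * V_f.

    alpha_i = 2 pi V_i / (h nu_imag).  Uses the cancellation-free identity
    cosh(a+b) - cosh(a-b) = 2 sinh a sinh b, so deep-tunneling
    probabilities are accurate in log space.
    """
    inv = 1.0 / math.sqrt(alpha1) + 1.0 / math.sqrt(alpha2)
    a = 2.0 * math.sqrt(max(alpha1 * xi, 0.0)) / inv
    b = 2.0 * math.sqrt(max(alpha1 * xi - alpha1 + alpha2, 0.0)) / inv
    if a == 0.0 or b == 0.0:
        return -math.inf
    d2 = alpha1 * alpha2 - math.pi**2 / 4.0
    sigma = a + b
    # ln(cosh(sigma) + cosh(d)) with d possibly imaginary (cosh -> cos)
    if d2 >= 0.0:
        d = 2.0 * math.sqrt(d2)
        m = max(sigma, d)
        ln_den = m - math.log(2.0) + math.log(
            math.exp(sigma - m)
            + math.exp(-sigma - m)
            + math.exp(d - m)
            + math.exp(-d - m)
        )
    else:
        cos_d = math.cos(2.0 * math.sqrt(-d2))
        ln_den = sigma - math.log(2.0) + math.log1p(
            math.exp(-2.0 * sigma) + 2.0 * cos_d * math.exp(-sigma)
        )
    return math.log(2.0) + _ln_sinh(a) + _ln_sinh(b) - ln_den


def eckart_kappa(
    V_forward: float,
    V_reverse: float,
    nu_imag: float,
    T: float,
    constants: PhysicalConstants = CODATA2018,
    epsrel: float = 1e-10,
) -> float:
    """Tunneling coefficient from an asymmetric Eckart barrier.

    The barrier is parametrised by the forward and reverse barrier heights
    (kcal/mol) and the imaginary wavenumber at the saddle (cm^-1); the
    transmission probability is Boltzmann-averaged,

        kappa(T) = exp(V_f/kBT)/kBT * int_{E0}^inf P(E) exp(-E/kBT) dE,

    with E0 the higher of the two asymptotes.  This is the documented
    desk-scale stand-in for a small-curvature-tunneling coefficient, which
    requires minimum-energy-path data not reproducible here.
    """
    if V_forward <= 0 or V_reverse <= 0:
        raise ValueError("barrier heights must be positive")
    if nu_imag <= 0:
        raise ValueError("imaginary wavenumber must be positive")
    if T <= 0:
        raise ValueError("temperature must be positive")
    h_nu = constants.wavenumber_to_kcalmol * nu_imag  # kcal/mol
    alpha1 = 2.0 * math.pi * V_forward / h_nu
    alpha2 = 2.0 * math.pi * V_reverse / h_nu
    kT = constants.thermal_energy(T)
    # integrate over x = (E - V_f)/kT so the Boltzmann weight exp(-x) is O(1)
    # near the barrier top, where P switches from ~0 to ~1
    x_min = -min(V_forward, V_reverse) / kT

    def integrand(x: float) -> float:
        xi = 1.0 + x * kT / V_forward
        ln_p = _ln_eckart_transmission(xi, alpha1, alpha2)
        return math.exp(ln_p - x) if math.isfinite(ln_p) else 0.0

    # split at the barrier top (x = 0), where the transmission probability
    # switches regimes, and integrate each side adaptively
    pieces = [
        integrate.quad(integrand, x_min, 0.0, epsrel=epsrel, epsabs=0.0, limit=1000),
        integrate.quad(
            integrand, 0.0, max(50.0, -2.0 * x_min), epsrel=epsrel, epsabs=0.0,
            limit=1000,
        ),
    ]
    value = sum(v for v, _ in pieces)
    abserr = sum(e for _, e in pieces)
    if not np.isfinite(value) or (value > 0 and abserr / value > 1e-6):
        raise RuntimeError(
            f"Eckart quadrature did not converge (value={value}, abserr={abserr})"
        )
    return float(value)


def catalytic_ratio(k_encapsulated: float, k_free: float) -> float:
    """phi = k[e] / k[f], the encapsulated-to-free rate-constant ratio."""
    if k_encapsulated <= 0 or k_free <= 0:
        raise ValueError("rate constants must be positive")
    return k_encapsulated / k_free


def barrier_factor(
    delta_V0: float,
    T: float = BODY_TEMPERATURE_K,
    constants: PhysicalConstants = CODATA2018,
) -> float:
    """Boltzmann estimate exp(-dV0 / kB T) of a barrier change's rate effect.

    A barrier lowered by 0.44 kcal/mol at 310.15 K gives ~2 (a twofold
    speed-up); a barrier raised by 0.48 kcal/mol gives ~0.46 (halving).
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    return math.exp(-delta_V0 / constants.thermal_energy(T))
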