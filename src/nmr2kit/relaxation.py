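"""Two-spin dipolar cross-relaxation physics.

Closed-form spectral densities, cross-relaxation-rate <-> distance
conversion, and isotropic rotational-correlation-time estimation from
15N relaxation rates.

Conventions
-----------
* The Lorentzian spectral density is ``J(w) = tau_c / (1 + w^2 tau_c^2)``
  so that ``J(0) == tau_c``.  The ``1/10`` prefactor of the dipolar
  cross-relaxation rate is carried explicitly in :func:`sigma_from_distance`
  (i.e. the 2/5-normalised convention is *not* used for the homonuclear
  expressions).
* SI units internally; distances are Angstrom at the API boundary only.
* In the slow-tumbling regime (``6 J(2w_H) < J(0)``) the cross-relaxation
  rate sigma is negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

__all__ = [
    "MU0",
    "HBAR",
    "GAMMA_H",
    "GAMMA_N",
    "RelaxationContext",
    "SpectralDensityValue",
    "spectral_density",
    "sigma_from_distance",
    "distance_from_sigma",
    "simulate_n15_rates",
    "estimate_tau_c",
]

# CODATA 2018 values (SI).
MU0 = 1.25663706212e-6  # vacuum permeability, N A^-2
HBAR = 1.054571817e-34  # reduced Planck constant, J s
GAMMA_H = 2.6752218744e8  # 1H gyromagnetic ratio, rad s^-1 T^-1
GAMMA_N = -2.7126189e7  # 15N gyromagnetic ratio, rad s^-1 T^-1

# Amide geometry / CSA used by the 15N tau_c estimator.
_R_NH = 1.02e-10  # N-H bond length, m
_CSA_N = -160.0e-6  # 15N chemical shift anisotropy

_ANGSTROM = 1e-10


class InvalidContextError(ValueError):
    """Raised when a RelaxationContext carries non-physical parameters."""


class NoSolutionError(ValueError):
    """Raised when a rate cannot be inverted to a distance."""


@dataclass(frozen=True)
class RelaxationContext:
    """Physical context for sigma <-> distance conversion.

    Parameters
    ----------
    tau_c:
        Rotational correlation time in seconds (isotropic rigid tumbling).
    proton_larmor:
        Angular 1H Larmor frequency omega_H in rad/s.  Use
        :meth:`from_field` to construct from a spectrometer frequency
        in MHz (e.g. 800 MHz -> 2*pi*800e6 rad/s).
    """

    tau_c: float
    proton_larmor: float
    mu0: float = field(default=MU0, init=False)
    hbar: float = field(default=HBAR, init=False)
    gamma_h: float = field(default=GAMMA_H, init=False)

    def __post_init__(self) -> None:
        if not (self.tau_c > 0.0 and math.isfinite(self.tau_c)):
            raise InvalidContextError(f"tau_c must be positive, got {self.tau_c!r}")
        if not (self.proton_larmor > 0.0 and math.isfinite(self.proton_larmor)):
            raise InvalidContextError(
                f"proton_larmor must be positive, got {self.proton_larmor!r}"
            )

    @classmethod
    def from_field(cls, tau_c: float, field_mhz: float) -> "RelaxationContext":
        """Build a context from tau_c (s) and a 1H frequency in MHz."""
        return cls(tau_c=tau_c, proton_larmor=2.0 * math.pi * field_mhz * 1e6)

    @property
    def dipolar_prefactor(self) -> float:
        """(mu0/4pi)^2 * hbar^2 * gamma_H^4 / 10, SI (m^6 s^-2)."""
        return (self.mu0 / (4.0 * math.pi)) ** 2 * self.hbar**2 * self.gamma_h**4 / 10.0


@dataclass(frozen=True)
class SpectralDensityValue:
    omega: float  # rad/s
    j: float  # seconds


def spectral_density(omega: float, ctx: RelaxationContext) -> SpectralDensityValue:
    """Lorentzian spectral density J(w) = tau_c / (1 + w^2 tau_c^2).

    ``J(0) == tau_c`` under this convention.
    """
    if omega < 0.0:
        raise ValueError(f"omega must be >= 0, got {omega!r}")
    j = ctx.tau_c / (1.0 + (omega * ctx.tau_c) ** 2)
    return SpectralDensityValue(omega=omega, j=j)


def _j(omega: float, tau_c: float) -> float:
    return tau_c / (1.0 + (omega * tau_c) ** 2)


def _sigma_j_term(ctx: RelaxationContext) -> float:
    """6 J(2 w_H) - J(0); negative for slow tumbling."""
    return 6.0 * _j(2.0 * ctx.proton_larmor, ctx.tau_c) - _j(0.0, ctx.tau_c)


def sigma_from_distance(r: float, ctx: RelaxationContext) -> float:
    """Homonuclear cross-relaxation rate for an isolated spin pair.

    sigma = (mu0/4pi)^2 hbar^2 gamma_H^4 / (10 r^6) * [6 J(2 w_H) - J(0)]

    Parameters
    ----------
    r:
        Interproton distance in Angstrom.

    Returns
    -------
    float
        sigma in s^-1 (negative in the slow-tumbling regime).
    """
    if not (r > 0.0 and math.isfinite(r)):
        raise ValueError(f"distance must be positive, got {r!r}")
    r_m = r * _ANGSTROM
    return ctx.dipolar_prefactor / r_m**6 * _sigma_j_term(ctx)


def distance_from_sigma(sigma: float, ctx: RelaxationContext) -> float:
    """Invert :func:`sigma_from_distance`; returns Angstrom.

    The sign of ``sigma`` must match the sign of ``6 J(2w) - J(0)`` for
    the given context (negative at tau_c >= ~1 ns and typical fields),
    otherwise there is no physical solution.
    """
    jterm = _sigma_j_term(ctx)
    if sigma == 0.0 or not math.isfinite(sigma):
        raise NoSolutionError(f"cannot invert sigma = {sigma!r}")
    if sigma * jterm <= 0.0:
        raise NoSolutionError(
            f"sigma = {sigma!r} has the wrong sign for this context "
            f"(6J(2w)-J(0) = {jterm:.3e})"
        )
    r_m6 = ctx.dipolar_prefactor * jterm / sigma
    return (r_m6 ** (1.0 / 6.0)) / _ANGSTROM


# ---------------------------------------------------------------------------
# 15N-based tau_c estimation (isotropic, Lorentzian spectral densities).
# ---------------------------------------------------------------------------


def _n15_rates(tau_c: float, field_mhz: float) -> tuple[float, float]:
    """Longitudinal and transverse 15N relaxation rates (dipolar + CSA).

    Model-free spectral density with S^2 = 1:  J(w) = (2/5) tau_c/(1+w^2 tau_c^2).
    R1rho is treated as R2 (no exchange contribution).
    """
    omega_h = 2.0 * math.pi * field_mhz * 1e6
    omega_n = omega_h * abs(GAMMA_N) / GAMMA_H

    def j(w: float) -> float:
        return 0.4 * tau_c / (1.0 + (w * tau_c) ** 2)

    d = (MU0 / (4.0 * math.pi)) * HBAR * GAMMA_H * abs(GAMMA_N) / _R_NH**3
    d2 = d * d
    c2 = (_CSA_N * omega_n) ** 2 / 3.0

    jhmn = j(omega_h - omega_n)
    jn = j(omega_n)
    jhpn = j(omega_h + omega_n)
    jh = j(omega_h)
    j0 = j(0.0)

    r1 = d2 / 4.0 * (jhmn + 3.0 * jn + 6.0 * jhpn) + c2 * jn
    r2 = d2 / 8.0 * (4.0 * j0 + jhmn + 3.0 * jn + 6.0 * jh + 6.0 * jhpn) + c2 / 6.0 * (
        4.0 * j0 + 3.0 * jn
    )
    return r1, r2


def simulate_n15_rates(tau_c: float, field_mhz: float) -> tuple[float, float]:
    """Forward-simulate (R1, R1rho) for an amide 15N at the given tau_c.

    Companion of :func:`estimate_tau_c`; used to generate synthetic
    relaxation data and for round-trip validation.
    """
    if tau_c <= 0.0:
        raise InvalidContextError(f"tau_c must be positive, got {tau_c!r}")
    return _n15_rates(tau_c, field_mhz)


def estimate_tau_c(
    t1_rate: float,
    t1rho_rate: float,
    field_mhz: float,
    *,
    tau_lo: float = 1e-13,
    tau_hi: float = 1e-6,
) -> float:
    """Isotropic tau_c from the 15N R2/R1 ratio.

    Solves the standard ratio relation under Lorentzian spectral
    densities by a root-find on a function that is monotone in tau_c.
    This is a simplified isotropic replacement for a full anisotropic
    diffusion analysis; R1rho is taken as R2 (no exchange term).

    Raises
    ------
    ValueError
        If the rate ratio lies below the theoretical minimum (extreme
        narrowing) or above the attainable range.
    """
    if t1_rate <= 0.0 or t1rho_rate <= 0.0:
        raise ValueError("relaxation rates must be positive")
    if t1rho_rate < t1_rate:
        raise ValueError("R1rho must be >= R1 for a physical ratio")
    target = t1rho_rate / t1_rate

    def f(tau: float) -> float:
        r1, r2 = _n15_rates(tau, field_mhz)
        return r2 / r1 - target

    f_lo, f_hi = f(tau_lo), f(tau_hi)
    if f_lo > 0.0:
        raise ValueError(
            f"R2/R1 = {target:.4f} is below the extreme-narrowing minimum "
            f"for this field; no tau_c solution"
        )
    if f_hi < 0.0:
        raise ValueError(f"R2/R1 = {target:.4f} exceeds the attainable range")
    return brentq(f, tau_lo, tau_hi, xtol=1e-18, rtol=8.9e-16)
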