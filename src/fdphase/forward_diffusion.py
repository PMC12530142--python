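"""Closed-form frequency-domain diffusion forward model.

Phase and amplitude of the photon-density wave launched by an
intensity-modulated point source in a highly scattering medium.  The complex
diffusion wavevector k = k_real + i·k_imag governs both: the detected-flux
phase is

    Φ(ρ) = k_imag·ρ − arctan( k_imag·ρ / (1 + k_real·ρ) )

(a positive lag, zero at the source), and ln(ρ²·U_AC) decays linearly in ρ
with slope −k_real.  Valid in the diffusion regime µs′ ≫ µa.

Units: coefficients in cm⁻¹, distances in cm, frequencies in Hz,
phases in radians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "C0_CM_PER_S",
    "FDContext",
    "DiffusionWavevector",
    "wavevector",
    "flux_phase",
    "model_amplitude",
]

#: Vacuum speed of light (cm/s).
C0_CM_PER_S = 2.99792458e10


@dataclass(frozen=True)
class FDContext:
    """Measurement context: modulation frequency, medium index, separation.

    ``omega`` (rad/s) and ``v`` (cm/s, in-medium light speed) are derived.
    ``f_mod = 0`` is allowed and collapses to the DC (zero-phase) limit.
    """

    f_mod: float
    n_medium: float = 1.37
    rho: float = 2.0

    def __post_init__(self) -> None:
        if self.f_mod < 0:
            raise ValueError("modulation frequency must be nonnegative")
        if self.n_medium <= 0:
            raise ValueError("refractive index must be positive")
        if self.rho < 0:
            raise ValueError("source-detector separation must be nonnegative")

    @property
    def omega(self) -> float:
        return 2.0 * np.pi * self.f_mod

    @property
    def v(self) -> float:
        return C0_CM_PER_S / self.n_medium


@dataclass(frozen=True)
class DiffusionWavevector:
    """Attenuation (k_real) and oscillatory (k_imag) parts plus D (cm)."""

    k_real: np.ndarray
    k_imag: np.ndarray
    D: np.ndarray


def wavevector(mu_a, mu_s_prime, ctx: FDContext) -> DiffusionWavevector:
    """Complex diffusion wavevector for given optical properties.

    D = 1/(3(µa + µs′));
    k_real = sqrt( (µa/2D)·(sqrt(1 + (ω/vµa)²) + 1) );
    k_imag = sqrt( (µa/2D)·(sqrt(1 + (ω/vµa)²) − 1) ).

    Satisfies k_real·k_imag = ω/(2vD) and k_real² − k_imag² = µa/D.
    """
    mu_a = np.asarray(mu_a, dtype=float)
    mu_s_prime = np.asarray(mu_s_prime, dtype=float)
    if np.any(mu_a <= 0):
        raise ValueError("mu_a must be positive (omega/(v*mu_a) diverges at 0)")
    if np.any(mu_s_prime <= 0):
        raise ValueError("mu_s_prime must be positive")
    D = 1.0 / (3.0 * (mu_a + mu_s_prime))
    ratio = ctx.omega / (ctx.v * mu_a)
    root = np.sqrt(1.0 + ratio**2)
    base = mu_a / (2.0 * D)
    k_real = np.sqrt(base * (root + 1.0))
    k_imag = np.sqrt(base * (root - 1.0))
    return DiffusionWavevector(k_real=k_real, k_imag=k_imag, D=D)


def flux_phase(mu_a, mu_s_prime, ctx: FDContext) -> np.ndarray:
    """Phase lag Φ (radians, ≥ 0) of the photon-density wave at separation ρ.

    Vectorized over arrays of (mu_a, mu_s_prime), e.g. per-wavelength
    spectra at a shared context.
    """
    k = wavevector(mu_a, mu_s_prime, ctx)
    kr_rho = k.k_real * ctx.rho
    ki_rho = k.k_imag * ctx.rho
    # arctan (not arctan2) is safe: the denominator 1 + k_real*rho >= 1
    return ki_rho - np.arctan(ki_rho / (1.0 + kr_rho))


def model_amplitude(mu_a, mu_s_prime, ctx: FDContext, dc: bool = False):
    """AC (or DC) amplitude surrogate U(ρ) = exp(−k_real·ρ)/ρ².

    The asymptotic spherical-wave form for which ln(ρ²·U) is exactly linear
    in ρ with slope −k_real; the DC amplitude is the same form at ω = 0.
    Arbitrary units — only ratios across ρ are meaningful.
    """
    if ctx.rho <= 0:
        raise ValueError("amplitude model requires rho > 0")
    if dc:
        ctx = FDContext(f_mod=0.0, n_medium=ctx.n_medium, rho=ctx.rho)
        # omega = 0 makes the ratio term vanish; k_real -> sqrt(mu_a/D)
    k = wavevector(mu_a, mu_s_prime, ctx)
    return np.exp(-k.k_real * ctx.rho) / ctx.rho**2
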