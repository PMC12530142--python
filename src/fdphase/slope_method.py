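"""Conventional multidistance FD-NIRS slope method.

At each wavelength, the phase and ln(ρ²·U_AC) of the photon-density wave
are linear in the source-detector separation ρ (slopes k_imag and −k_real
of the complex diffusion wavevector).  Ordinary least-squares slopes across
the measured separations are converted to (µa, µs′) through the
infinite-medium frequency-domain diffusion relations

    µa  = (ω/2v)·(k_r/k_i − k_i/k_r),   D = ω/(2·v·k_r·k_i),
    µs′ = 1/(3D) − µa,        with k_r = −s_AC,  k_i = s_phase,

and the per-wavelength absorption spectrum is unmixed into chromophore
concentrations via the Beer–Lambert extinction matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forward_diffusion import C0_CM_PER_S
from .spectra import ExtinctionTable, OpticalProperties, unmix_concentrations

__all__ = ["SlopePair", "fit_slopes", "slopes_to_optics", "slope_pipeline"]


@dataclass(frozen=True)
class SlopePair:
    """OLS slopes of phase and ln(ρ²·AC) versus ρ at one wavelength."""

    s_ac: float     # cm^-1, negative for physical media
    s_phase: float  # rad/cm, positive for physical media
    r2_ac: float
    r2_phase: float
    wavelength: float


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), r2


def fit_slopes(measurements: pd.DataFrame) -> SlopePair:
    """Fit the two multidistance slopes for one wavelength.

    ``measurements`` must contain columns rho_cm, ac, phase_rad for a
    single wavelength, with at least two distinct separations.
    """
    rho = measurements["rho_cm"].to_numpy(dtype=float)
    ac = measurements["ac"].to_numpy(dtype=float)
    phase = measurements["phase_rad"].to_numpy(dtype=float)
    if np.unique(rho).size < 2:
        raise ValueError("slope fit needs measurements at >= 2 distinct separations")
    if not (np.all(np.isfinite(ac)) and np.all(np.isfinite(phase))):
        raise ValueError("nonfinite measurement values")
    if np.any(ac <= 0):
        raise ValueError("AC amplitudes must be positive to take the log")
    wl = measurements["wavelength_nm"].to_numpy(dtype=float)
    if np.unique(wl).size != 1:
        raise ValueError("fit_slopes expects a single wavelength")
    s_ac, r2_ac = _ols(rho, np.log(rho**2 * ac))
    s_phase, r2_phase = _ols(rho, phase)
    return SlopePair(
        s_ac=s_ac, s_phase=s_phase, r2_ac=r2_ac, r2_phase=r2_phase,
        wavelength=float(wl[0]),
    )


def slopes_to_optics(
    sp: SlopePair, f_mod: float = 110e6, n_medium: float = 1.37
) -> tuple[float, float]:
    """Convert a slope pair to (µa, µs′) in cm⁻¹.

    Requires s_ac < 0 < s_phase and |s_ac| > s_phase; otherwise the implied
    absorption is nonpositive and a ``ValueError`` is raised.
    """
    k_r = -sp.s_ac
    k_i = sp.s_phase
    if k_r <= 0 or k_i <= 0:
        raise ValueError("expected s_ac < 0 and s_phase > 0")
    if k_i >= k_r:
        raise ValueError("nonphysical slopes: phase slope >= attenuation slope")
    omega = 2.0 * np.pi * f_mod
    v = C0_CM_PER_S / n_medium
    mu_a = (omega / (2.0 * v)) * (k_r / k_i - k_i / k_r)
    D = omega / (2.0 * v * k_r * k_i)
    mu_s_prime = 1.0 / (3.0 * D) - mu_a
    return float(mu_a), float(mu_s_prime)


def slope_pipeline(
    measurements: pd.DataFrame,
    table: ExtinctionTable,
    water_fraction: float = 0.75,
    f_mod: float = 110e6,
    n_medium: float = 1.37,
    radii: tuple[float, ...] | None = None,
    n_chromophores: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Slope method over a full FD measurement table.

    For every sample: fit slopes per wavelength, convert to optical
    properties, then unmix concentrations.  Returns ``(optics, conc)``
    frames with columns (sample_id, wavelength_nm, mu_a_est, mu_sp_est)
    and (sample_id, hbo_est, hb_est, cco_est).

    ``radii`` restricts the fit to a subset of separations (e.g. a
    three-distance variant dropping 3.5 cm).
    """
    df = measurements
    if radii is not None:
        df = df[df["rho_cm"].isin(radii)]
    optics_rows, conc_rows = [], []
    for sample_id, sdf in df.groupby("sample_id", sort=False):
        wls = np.sort(sdf["wavelength_nm"].unique())
        mu_a_est, mu_sp_est = [], []
        for lam in wls:
            wdf = sdf[sdf["wavelength_nm"] == lam]
            if wdf["rho_cm"].nunique() < 2:
                raise ValueError(
                    f"sample {sample_id}: wavelength {lam} nm present at "
                    "fewer than 2 separations"
                )
            sp = fit_slopes(wdf)
            mu_a, mu_sp = slopes_to_optics(sp, f_mod=f_mod, n_medium=n_medium)
            mu_a_est.append(mu_a)
            mu_sp_est.append(mu_sp)
            optics_rows.append((sample_id, lam, mu_a, mu_sp))
        optics = OpticalProperties(
            wavelengths=wls, mu_a=np.array(mu_a_est), mu_s_prime=np.array(mu_sp_est)
        )
        c = unmix_concentrations(
            optics, table, water_fraction=water_fraction,
            n_chromophores=n_chromophores,
        )
        conc_rows.append((sample_id, c.hbo, c.hb, c.cco_redox))
    return (
        pd.DataFrame(
            optics_rows, columns=["sample_id", "wavelength_nm", "mu_a_est", "mu_sp_est"]
        ),
        pd.DataFrame(conc_rows, columns=["sample_id", "hbo_est", "hb_est", "cco_est"]),
    )
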