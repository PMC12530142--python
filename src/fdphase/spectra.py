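"""Spectral parameterization of tissue optical properties.

Maps a small set of wavelength-independent physiological parameters —
chromophore concentrations and a power-law scattering prescription — onto
wavelength-resolved absorption and reduced scattering coefficients, and
inverts the linear absorption model (Beer–Lambert unmixing).

Units: concentrations in µM, extinction coefficients in cm⁻¹µM⁻¹,
absorption/scattering coefficients in cm⁻¹, lengths in cm, wavelengths in nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ChromophoreSet",
    "ScatterLaw",
    "ExtinctionTable",
    "OpticalProperties",
    "TWO_WAVELENGTHS",
    "EIGHT_WAVELENGTHS",
    "load_default_extinction_table",
    "absorption_spectrum",
    "scattering_spectrum",
    "unmix_concentrations",
]

#: Dual-wavelength configuration used for hemoglobin-only estimation (nm).
TWO_WAVELENGTHS = (690.0, 830.0)

#: Eight-wavelength configuration used when the cytochrome-c-oxidase redox
#: difference is estimated alongside the hemoglobins (nm).
EIGHT_WAVELENGTHS = (784.0, 800.0, 818.0, 835.0, 851.0, 868.0, 881.0, 894.0)


@dataclass(frozen=True)
class ChromophoreSet:
    """Tissue chromophore composition for one sample.

    Attributes
    ----------
    hbo, hb : float
        Oxy- and deoxy-hemoglobin concentrations (µM); must be nonnegative.
    cco_redox : float
        Differential redox-state concentration of cytochrome c oxidase,
        oxidized minus reduced (µM). May in principle take either sign.
    water_fraction : float
        Volume fraction of water treated as a fixed absorption background
        (dimensionless, 0–1); never a fitted quantity.
    """

    hbo: float
    hb: float
    cco_redox: float = 0.0
    water_fraction: float = 0.75

    def __post_init__(self) -> None:
        if self.hbo < 0 or self.hb < 0:
            raise ValueError("hemoglobin concentrations must be nonnegative")
        if not 0.0 <= self.water_fraction <= 1.0:
            raise ValueError("water_fraction must lie in [0, 1]")

    def as_vector(self) -> np.ndarray:
        """Concentration vector in fixed (HbO, Hb, CCOredox) order."""
        return np.array([self.hbo, self.hb, self.cco_redox], dtype=float)


@dataclass(frozen=True)
class ScatterLaw:
    """Power-law reduced-scattering prescription µs′(λ) = a·(λ/λ0)^(−b).

    ``a`` is the reduced scattering coefficient (cm⁻¹) at the reference
    wavelength ``lambda0`` (nm); ``b`` is the dimensionless scattering power.
    """

    a: float
    b: float
    lambda0: float = 500.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("scattering amplitude a must be positive")
        if self.lambda0 <= 0:
            raise ValueError("reference wavelength must be positive")


class ExtinctionTable:
    """Molar extinction coefficients and water absorption on a wavelength grid.

    Columns of ``epsilon`` follow the fixed chromophore order
    (HbO, Hb, CCOredox difference).  All coefficients use the natural-log
    convention so that µa = Σ ε_i·C_i directly, in cm⁻¹.
    """

    CHROMOPHORES = ("hbo", "hb", "cco_redox")

    def __init__(
        self,
        wavelengths: np.ndarray,
        epsilon: np.ndarray,
        mu_a_water: np.ndarray,
    ) -> None:
        wavelengths = np.asarray(wavelengths, dtype=float)
        epsilon = np.asarray(epsilon, dtype=float)
        mu_a_water = np.asarray(mu_a_water, dtype=float)
        if np.any(np.diff(wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if epsilon.shape != (wavelengths.size, 3):
            raise ValueError("epsilon must have one row per wavelength and 3 columns")
        if np.any(epsilon[:, :2] < 0):
            raise ValueError("hemoglobin extinction coefficients must be nonnegative")
        self.wavelengths = wavelengths
        self.epsilon = epsilon
        self.mu_a_water = mu_a_water

    @classmethod
    def from_csv(cls, path_or_buffer) -> "ExtinctionTable":
        df = pd.read_csv(path_or_buffer, comment="#")
        return cls(
            df["wavelength_nm"].to_numpy(),
            df[["eps_hbo", "eps_hb", "eps_ccodiff"]].to_numpy(),
            df["mua_water"].to_numpy(),
        )

    def _indices(self, wavelengths) -> np.ndarray:
        wl = np.atleast_1d(np.asarray(wavelengths, dtype=float))
        idx = np.searchsorted(self.wavelengths, wl)
        bad = (idx >= self.wavelengths.size) | ~np.isclose(
            self.wavelengths[np.clip(idx, 0, self.wavelengths.size - 1)], wl
        )
        if np.any(bad):
            missing = wl[bad]
            raise KeyError(
                f"wavelength(s) {missing.tolist()} nm not present in extinction table"
            )
        return idx

    def epsilon_at(self, wavelengths) -> np.ndarray:
        """Extinction matrix rows (n_wavelengths × 3) at the given wavelengths."""
        return self.epsilon[self._indices(wavelengths)]

    def water_at(self, wavelengths) -> np.ndarray:
        """Pure-water absorption (cm⁻¹) at the given wavelengths."""
        return self.mu_a_water[self._indices(wavelengths)]


@dataclass(frozen=True)
class OpticalProperties:
    """Per-wavelength absorption and reduced scattering coefficients (cm⁻¹)."""

    wavelengths: np.ndarray
    mu_a: np.ndarray
    mu_s_prime: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "wavelengths", np.asarray(self.wavelengths, float))
        object.__setattr__(self, "mu_a", np.asarray(self.mu_a, float))
        object.__setattr__(self, "mu_s_prime", np.asarray(self.mu_s_prime, float))
        if np.any(self.mu_a < 0):
            raise ValueError("mu_a must be nonnegative")
        if np.any(self.mu_s_prime <= 0):
            raise ValueError("mu_s_prime must be positive")


def load_default_extinction_table() -> ExtinctionTable:
    """Load the packaged 10-wavelength extinction fixture."""
    ref = resources.files("fdphase.data") / "extinction_nir.csv"
    with ref.open("r") as fh:
        return ExtinctionTable.from_csv(fh)


def absorption_spectrum(
    c: ChromophoreSet, table: ExtinctionTable, wavelengths
) -> np.ndarray:
    """Absorption coefficient µa(λ) = Σ_i ε_i(λ)·C_i + f_water·µa_water(λ).

    Returns one value (cm⁻¹) per requested wavelength; raises ``KeyError``
    if a wavelength is absent from the table.
    """
    eps = table.epsilon_at(wavelengths)
    water = table.water_at(wavelengths)
    return eps @ c.as_vector() + c.water_fraction * water


def scattering_spectrum(s: ScatterLaw, wavelengths) -> np.ndarray:
    """Reduced scattering coefficient µs′(λ) = a·(λ/λ0)^(−b) (cm⁻¹).

    With b > 0 scattering decreases with wavelength, the physical behavior
    of soft tissue in the NIR.
    """
    wl = np.atleast_1d(np.asarray(wavelengths, dtype=float))
    if np.any(wl <= 0):
        raise ValueError("wavelengths must be positive")
    return s.a * (wl / s.lambda0) ** (-s.b)


def unmix_concentrations(
    optics: OpticalProperties,
    table: ExtinctionTable,
    water_fraction: float = 0.75,
    n_chromophores: int | None = None,
) -> ChromophoreSet:
    """Recover chromophore concentrations from an absorption spectrum.

    Solves the linear system ε·C = µa − f_water·µa_water in the
    least-squares sense.  With two wavelengths only the two hemoglobin
    species are solved (CCOredox fixed at zero); with three or more
    wavelengths all three chromophores are recovered unless
    ``n_chromophores`` says otherwise.
    """
    wl = optics.wavelengths
    if n_chromophores is None:
        n_chromophores = 3 if wl.size >= 3 else 2
    if wl.size < n_chromophores:
        raise ValueError(
            f"need at least {n_chromophores} wavelengths to solve "
            f"{n_chromophores} chromophores, got {wl.size}"
        )
    eps = table.epsilon_at(wl)[:, :n_chromophores]
    if np.linalg.matrix_rank(eps) < n_chromophores:
        raise np.linalg.LinAlgError("extinction matrix is rank deficient")
    rhs = optics.mu_a - water_fraction * table.water_at(wl)
    conc, *_ = np.linalg.lstsq(eps, rhs, rcond=None)
    full = np.zeros(3)
    full[:n_chromophores] = conc
    return _unchecked_chromophores(full, water_fraction)


def _unchecked_chromophores(vec: np.ndarray, water_fraction: float) -> ChromophoreSet:
    # Estimated concentrations can legitimately come out slightly negative
    # under noise; bypass the nonnegativity guard meant for ground truth.
    obj = object.__new__(ChromophoreSet)
    object.__setattr__(obj, "hbo", float(vec[0]))
    object.__setattr__(obj, "hb", float(vec[1]))
    object.__setattr__(obj, "cco_redox", float(vec[2]))
    object.__setattr__(obj, "water_fraction", float(water_fraction))
    return obj
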