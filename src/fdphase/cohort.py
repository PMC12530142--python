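"""Synthetic cohort generation, error metrics and the experiment runner.

The cohort emulates inter-subject variability in tissue composition:
chromophore concentrations drawn from Gaussians around physiological means
(HbO 60, Hb 25, CCOredox 8.5 µM; SD 10% of the mean, truncated at zero),
water fixed at a 75% volume fraction, and power-law scattering parameters
(a = 24.2 cm⁻¹, b = 1.611 at λ0 = 500 nm) each perturbed with SD 1% of the
base value.  Thirty samples is the default cohort size.

Two forward models produce the FD measurement table: the closed-form
diffusion surrogate (phases from the flux-phase model, amplitudes from the
asymptotic exp(−k_r·ρ)/ρ² form, optional additive Gaussian phase noise)
and the time-resolved Monte Carlo engine.  The experiment runner applies
the multidistance slope method and the single-distance phase-only
inversion independently at each separation (SD1–SD4), and reports MAE and
MRE per chromophore, method and separation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .fd1sd import fit_fd1sd
from .forward_diffusion import FDContext, flux_phase, model_amplitude
from .mc_forward import MCGeometry, forward_cohort_mc
from .slope_method import slope_pipeline
from .spectra import (
    EIGHT_WAVELENGTHS,
    TWO_WAVELENGTHS,
    ChromophoreSet,
    ExtinctionTable,
    ScatterLaw,
    absorption_spectrum,
    load_default_extinction_table,
    scattering_spectrum,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CohortConfig",
    "TissueSample",
    "generate_cohort",
    "forward_surrogate",
    "evaluate",
    "run_experiment",
]


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-generation settings (defaults are the study conditions)."""

    n_samples: int = 30
    mean_hbo: float = 60.0
    mean_hb: float = 25.0
    mean_cco: float = 8.5
    concentration_cv: float = 0.10
    water_fraction: float = 0.75
    scatter_a: float = 24.2
    scatter_b: float = 1.611
    lambda0: float = 500.0
    scatter_cv: float = 0.01
    wavelength_set: Literal["two", "eight"] = "eight"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.concentration_cv < 0 or self.scatter_cv < 0:
            raise ValueError("coefficients of variation must be nonnegative")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.array(
            TWO_WAVELENGTHS if self.wavelength_set == "two" else EIGHT_WAVELENGTHS
        )


@dataclass(frozen=True)
class TissueSample:
    """One simulated subject: composition, scattering law, derived optics."""

    sample_id: str
    chromophores: ChromophoreSet
    scatter: ScatterLaw
    wavelengths: np.ndarray
    table: ExtinctionTable = field(repr=False, default=None)

    def optics(self, wavelengths=None) -> tuple[np.ndarray, np.ndarray]:
        wl = np.asarray(
            self.wavelengths if wavelengths is None else wavelengths, float
        )
        mu_a = absorption_spectrum(self.chromophores, self.table, wl)
        mu_s = scattering_spectrum(self.scatter, wl)
        return mu_a, mu_s


def generate_cohort(
    cfg: CohortConfig, table: ExtinctionTable | None = None
) -> list[TissueSample]:
    """Draw a reproducible synthetic cohort.

    Concentrations are Normal(mean, cv·mean) truncated at zero; scattering
    parameters Normal(base, scatter_cv·base).  In the two-wavelength
    (hemoglobin-only) configuration CCOredox is zero by construction — that
    study models HbO, Hb and water only.
    """
    if table is None:
        table = load_default_extinction_table()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    hbo = np.clip(rng.normal(cfg.mean_hbo, cfg.concentration_cv * cfg.mean_hbo, n), 0, None)
    hb = np.clip(rng.normal(cfg.mean_hb, cfg.concentration_cv * cfg.mean_hb, n), 0, None)
    if cfg.wavelength_set == "two":
        cco = np.zeros(n)
    else:
        cco = np.clip(
            rng.normal(cfg.mean_cco, cfg.concentration_cv * cfg.mean_cco, n), 0, None
        )
    a = rng.normal(cfg.scatter_a, cfg.scatter_cv * cfg.scatter_a, n)
    b = rng.normal(cfg.scatter_b, cfg.scatter_cv * cfg.scatter_b, n)
    samples = []
    for i in range(n):
        samples.append(
            TissueSample(
                sample_id=f"S{i + 1:03d}",
                chromophores=ChromophoreSet(
                    hbo=float(hbo[i]), hb=float(hb[i]), cco_redox=float(cco[i]),
                    water_fraction=cfg.water_fraction,
                ),
                scatter=ScatterLaw(a=float(a[i]), b=float(b[i]), lambda0=cfg.lambda0),
                wavelengths=cfg.wavelengths,
                table=table,
            )
        )
    return samples


def truth_table(samples: list[TissueSample]) -> pd.DataFrame:
    """Ground-truth table persisted beside every set of estimates."""
    return pd.DataFrame(
        [
            (
                s.sample_id,
                s.chromophores.hbo,
                s.chromophores.hb,
                s.chromophores.cco_redox,
                s.scatter.a,
                s.scatter.b,
            )
            for s in samples
        ],
        columns=["sample_id", "hbo", "hb", "cco", "a", "b"],
    )


def forward_surrogate(
    samples: list[TissueSample],
    radii: tuple[float, ...] = (2.0, 2.5, 3.0, 3.5),
    f_mod: float = 110e6,
    n_medium: float = 1.37,
    phase_noise_sd: float = 0.0,
    noise_seed: int = 0,
) -> pd.DataFrame:
    """Closed-form forward data: Eq-of-motion phases + asymptotic amplitudes.

    Optionally adds zero-mean Gaussian noise (SD ``phase_noise_sd``, rad)
    to every phase value; amplitudes are left noiseless.
    """
    rng = np.random.default_rng(noise_seed)
    rows = []
    for s in samples:
        mu_a, mu_s = s.optics()
        for rho in radii:
            ctx = FDContext(f_mod=f_mod, n_medium=n_medium, rho=rho)
            ph = flux_phase(mu_a, mu_s, ctx)
            ac = model_amplitude(mu_a, mu_s, ctx)
            dc = model_amplitude(mu_a, mu_s, ctx, dc=True)
            if phase_noise_sd > 0:
                ph = ph + rng.normal(0.0, phase_noise_sd, ph.shape)
            for j, lam in enumerate(s.wavelengths):
                rows.append(
                    (s.sample_id, float(lam), rho, f_mod, dc[j], ac[j], ph[j])
                )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "wavelength_nm", "rho_cm", "f_mod_hz", "dc", "ac", "phase_rad",
        ],
    )


def evaluate(est: pd.DataFrame, truth: pd.DataFrame, params=None) -> pd.DataFrame:
    """MAE and MRE of estimates against ground truth, per parameter.

    ``est`` columns must be named ``<param>_est``; the frames are joined on
    sample_id and every pair must match.  MRE is the mean over samples of
    |est − truth|/truth in percent.
    """
    merged = est.merge(truth, on="sample_id", how="outer", indicator=True)
    if (merged["_merge"] != "both").any():
        missing = merged.loc[merged["_merge"] != "both", "sample_id"].tolist()
        raise ValueError(f"unmatched sample_ids: {missing}")
    if params is None:
        params = [
            c[: -len("_est")] for c in est.columns if c.endswith("_est")
            if c[: -len("_est")] in truth.columns
        ]
    rows = []
    for p in params:
        err = np.abs(merged[f"{p}_est"].to_numpy() - merged[p].to_numpy())
        rel = err / merged[p].to_numpy()
        rows.append((p, float(np.mean(err)), float(np.mean(rel) * 100.0)))
    return pd.DataFrame(rows, columns=["parameter", "mae", "mre_pct"])


def run_experiment(
    cfg: CohortConfig,
    forward: Literal["surrogate", "mc"] = "surrogate",
    radii: tuple[float, ...] = (2.0, 2.5, 3.0, 3.5),
    phase_noise_sd: float = 0.0035,
    n_photons: int = 200_000,
    f_mod: float = 110e6,
    n_medium: float = 1.37,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Full method comparison: slope method vs FD1SD_phase at each separation.

    Generates the cohort, produces forward FD data, runs both inversions,
    and evaluates MAE/MRE per chromophore for the slope method (``slope``)
    and the single-distance fits (``SD1``..``SDn``, one per separation).
    Returns a dict with the truth/measurement/estimate/error frames; writes
    them as CSV plus a key=value manifest when ``out_dir`` is given.
    """
    seed = cfg.seed if seed is None else seed
    cfg = replace(cfg, seed=seed)
    table = load_default_extinction_table()
    samples = generate_cohort(cfg, table)
    truth = truth_table(samples)
    mode = "two_wavelength" if cfg.wavelength_set == "two" else "eight_wavelength"
    n_chrom = 2 if cfg.wavelength_set == "two" else 3

    if forward == "surrogate":
        meas = forward_surrogate(
            samples, radii=radii, f_mod=f_mod, n_medium=n_medium,
            phase_noise_sd=phase_noise_sd, noise_seed=seed + 1,
        )
    elif forward == "mc":
        if n_photons < 1e5:
            logger.warning(
                "MC forward with only %d photons per channel: FD estimates "
                "will be noisy", n_photons,
            )
        meas = forward_cohort_mc(
            samples, MCGeometry(detector_radii=tuple(radii)),
            wavelengths=cfg.wavelengths, n_photons=n_photons,
            f_mod=f_mod, seed=seed + 1,
        )
    else:
        raise ValueError(f"unknown forward model {forward!r}")

    # conventional multidistance baseline (needs >= 2 separations)
    if len(set(radii)) >= 2:
        _, slope_conc = slope_pipeline(
            meas, table, water_fraction=cfg.water_fraction, f_mod=f_mod,
            n_medium=n_medium, n_chromophores=n_chrom,
        )
    else:
        logger.info("single separation configured: slope baseline skipped")
        slope_conc = None

    # single-distance phase-only fits, independently per separation
    fd_rows = []
    noise_hint = phase_noise_sd if (forward == "surrogate" and phase_noise_sd > 0) else None
    for s in samples:
        sdf = meas[meas["sample_id"] == s.sample_id]
        for rho in radii:
            rdf = sdf[sdf["rho_cm"] == rho].sort_values("wavelength_nm")
            fit = fit_fd1sd(
                rdf["phase_rad"].to_numpy(),
                rdf["wavelength_nm"].to_numpy(),
                rho=rho, f_mod=f_mod, mode=mode, table=table,
                phase_noise_sd=noise_hint,
                water_fraction=cfg.water_fraction, lambda0=cfg.lambda0,
                n_medium=n_medium,
            )
            fd_rows.append(
                (
                    s.sample_id, rho, mode,
                    fit.theta["hbo"], fit.theta["hb"],
                    fit.theta.get("cco_redox", 0.0),
                    fit.theta["a"], fit.theta["b"],
                    fit.final_cost, fit.converged,
                )
            )
    fd_results = pd.DataFrame(
        fd_rows,
        columns=[
            "sample_id", "rho_cm", "mode", "hbo_est", "hb_est", "cco_est",
            "a_est", "b_est", "final_cost", "converged",
        ],
    )

    chrom_params = ["hbo", "hb"] + (["cco"] if n_chrom == 3 else [])
    reports = []
    if slope_conc is not None:
        rep = evaluate(slope_conc, truth, params=chrom_params)
        rep.insert(0, "method", "slope")
        reports.append(rep)
    for i, rho in enumerate(radii, start=1):
        sub = fd_results[fd_results["rho_cm"] == rho]
        rep = evaluate(
            sub[["sample_id", "hbo_est", "hb_est", "cco_est"]], truth,
            params=chrom_params,
        )
        rep.insert(0, "method", f"SD{i}")
        reports.append(rep)
    error_report = pd.concat(reports, ignore_index=True)

    result = {
        "truth": truth,
        "measurements": meas,
        "slope_results": slope_conc,
        "fd1sd_results": fd_results,
        "error_report": error_report,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        truth.to_csv(out / "truth.csv", index=False)
        meas.to_csv(out / "measurements.csv", index=False)
        if slope_conc is not None:
            slope_conc.to_csv(out / "slope_results.csv", index=False)
        fd_results.to_csv(out / "fd1sd_results.csv", index=False)
        error_report.to_csv(out / "error_report.csv", index=False)
        manifest = {
            "seed": seed,
            "forward": forward,
            "wavelength_set": cfg.wavelength_set,
            "n_samples": cfg.n_samples,
            "phase_noise_sd": phase_noise_sd if forward == "surrogate" else "n/a",
            "n_photons": n_photons if forward == "mc" else "n/a",
            "radii_cm": ",".join(str(r) for r in radii),
            "f_mod_hz": f_mod,
        }
        with open(out / "manifest.txt", "w") as fh:
            for k, v in manifest.items():
                fh.write(f"{k}={v}\n")
    return result
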