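import numpy as np
import pytest

from fdphase.spectra import (
    ChromophoreSet,
    ScatterLaw,
    load_default_extinction_table,
)


@pytest.fixture(scope="session")
def table():
    return load_default_extinction_table()


@pytest.fixture(scope="session")
def typical_chromophores():
    """Cohort-mean composition: HbO 60, Hb 25, CCOredox 8.5 µM, 75% water."""
    return ChromophoreSet(hbo=60.0, hb=25.0, cco_redox=8.5, water_fraction=0.75)


@pytest.fixture(scope="session")
def typical_scatter():
    """Cohort-base power law: a = 24.2 cm^-1, b = 1.611, lambda0 = 500 nm."""
    return ScatterLaw(a=24.2, b=1.611, lambda0=500.0)


@pytest.fixture(scope="session")
def typical_optics():
    """Diffusion-regime optics used across forward-model tests (cm^-1)."""
    return 0.1, 10.0


@pytest.fixture(scope="session")
def reference_tpsf():
    """One 2x10^5-photon TPSF at rho = 2 cm, mu_a=0.1, mu_s'=10 (typical optics)."""
    from fdphase.mc_forward import MCGeometry, simulate_tpsf

    return simulate_tpsf(
        0.1, 10.0, MCGeometry(detector_radii=(2.0,)), n_photons=200_000, seed=42
    )[0]
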