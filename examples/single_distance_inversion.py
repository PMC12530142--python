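"""Single-distance, phase-only recovery of chromophore concentrations.

Generates phases for one synthetic tissue at the eight wavelengths and one
2.0 cm separation, then runs the bounded phase-only fit — first on clean
phases (exact recovery), then with 0.0035 rad Gaussian phase noise to show
how measurement noise degrades the estimates.
"""

import numpy as np

from fdphase import (
    ChromophoreSet,
    EIGHT_WAVELENGTHS,
    FDContext,
    ScatterLaw,
    absorption_spectrum,
    fit_fd1sd,
    flux_phase,
    load_default_extinction_table,
    scattering_spectrum,
)

table = load_default_extinction_table()
truth = ChromophoreSet(hbo=66.0, hb=22.0, cco_redox=9.0, water_fraction=0.75)
scatter = ScatterLaw(a=24.0, b=1.6, lambda0=500.0)

wl = np.array(EIGHT_WAVELENGTHS)
phases = flux_phase(
    absorption_spectrum(truth, table, wl),
    scattering_spectrum(scatter, wl),
    FDContext(f_mod=110e6, n_medium=1.37, rho=2.0),
)

print("truth:     HbO=66.00  Hb=22.00  CCOredox=9.00  a=24.00  b=1.600")
clean = fit_fd1sd(phases, wl, rho=2.0, mode="eight_wavelength")
t = clean.theta
print(
    f"clean fit: HbO={t['hbo']:.2f}  Hb={t['hb']:.2f}  "
    f"CCOredox={t['cco_redox']:.2f}  a={t['a']:.2f}  b={t['b']:.3f}  "
    f"(residual {clean.data_term:.2e} rad^2)"
)

rng = np.random.default_rng(0)
noisy_phases = phases + rng.normal(0.0, 0.0035, phases.shape)
noisy = fit_fd1sd(
    noisy_phases, wl, rho=2.0, mode="eight_wavelength", phase_noise_sd=0.0035
)
t = noisy.theta
print(
    f"noisy fit: HbO={t['hbo']:.2f}  Hb={t['hb']:.2f}  "
    f"CCOredox={t['cco_redox']:.2f}  a={t['a']:.2f}  b={t['b']:.3f}"
)

# Clean phases are reproduced essentially exactly (the five parameters are
# identifiable from eight noiseless phases).  With 0.0035 rad noise the
# near-degenerate joint scale of absorbers and scattering amplitude is no
# longer resolved, and estimates drift at the several-percent level.
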