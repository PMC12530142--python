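"""Time-resolved Monte Carlo forward model and FD extraction.

Simulates 2x10^5 photons through a 10 cm tissue cube (g = 0.85, n = 1.37)
for typical optics, extracts DC/AC/phase at 110 MHz from the detected
temporal point spread function, and compares the phase with the
closed-form diffusion model.
"""

from fdphase import FDContext, flux_phase
from fdphase.mc_forward import MCGeometry, fd_from_tpsf, simulate_tpsf

mu_a, mu_s_prime = 0.1, 10.0  # cm^-1
geom = MCGeometry(detector_radii=(2.0, 2.5))
tpsfs = simulate_tpsf(mu_a, mu_s_prime, geom, n_photons=200_000, seed=42)

for tp in tpsfs:
    m = fd_from_tpsf(tp, f_mod=110e6)
    phi = float(flux_phase(mu_a, mu_s_prime, FDContext(110e6, 1.37, tp.detector_radius)))
    print(
        f"rho={tp.detector_radius} cm: detected weight={tp.weights.sum():8.2f}  "
        f"MC phase={m.phase:.4f} rad  diffusion phase={phi:.4f} rad  "
        f"modulation depth={m.ac / m.dc:.3f}"
    )

# The Monte Carlo phase (with index-mismatched boundary and finite cube)
# agrees with the infinite-medium flux phase to a few hundredths of a
# radian at these separations; the residual is the boundary effect the
# closed-form model omits.  Detected weight falls sharply with rho, which
# is why desk-scale budgets get noisy beyond ~3 cm.
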