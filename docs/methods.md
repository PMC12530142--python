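# Methods

## Forward model

The frequency-domain forward model is the infinite-medium diffusion
photon-density wave. For absorption `µa` (cm⁻¹), reduced scattering `µs′`
(cm⁻¹), diffusion coefficient `D = 1/(3(µa + µs′))` (cm), modulation
frequency `ω = 2πf` and in-medium light speed `v = c0/n`
(c0 = 29.9792458 cm/ns, n = 1.37), the complex wavevector components are

    k_r = sqrt((µa/2D)(sqrt(1 + (ω/vµa)²) + 1)),
    k_i = sqrt((µa/2D)(sqrt(1 + (ω/vµa)²) − 1)),

satisfying `k_r k_i = ω/(2vD)` and `k_r² − k_i² = µa/D` (both are regression
targets in the test suite). The detected-flux phase is
`Φ = k_i ρ − arctan(k_i ρ/(1 + k_r ρ))`, a positive lag that vanishes at
ρ = 0 and at DC. No extrapolated-boundary image source is included: the same
expression is used in the forward direction and inside the inversion, so the
validation exercises internal consistency rather than boundary-model
fidelity; the Monte Carlo engine (which *does* have an index-mismatched
boundary) quantifies the resulting model error — about 0.01–0.03 rad at
2–2.5 cm for cohort-typical optics.

The amplitude surrogate `U(ρ) = exp(−k_r ρ)/ρ²` is the asymptotic spherical
wave for which `ln(ρ²U)` is exactly linear in ρ with slope −k_r. It exists so
the slope method can run on closed-form data; amplitude plays no role in the
single-distance inversion.

Phases are radians internally; lengths cm; concentrations µM; extinction
coefficients cm⁻¹µM⁻¹ in the natural-log convention (µa = Σ ε_i C_i
directly).

## Spectral parameterization

`µa(λ) = Σ ε_i(λ) C_i + f_w µa,water(λ)` over HbO, Hb and the
oxidized-minus-reduced cytochrome-c-oxidase difference spectrum, with the
water volume fraction fixed at 0.75 (never fitted, and included in both the
two- and eight-wavelength configurations). `µs′(λ) = a(λ/λ0)^(−b)` with
λ0 = 500 nm; the negative exponent with b > 0 makes scattering decrease with
wavelength, the physical convention for soft tissue, and is used identically
in forward and inverse directions.

The packaged extinction table (`src/fdphase/data/extinction_nir.csv`) holds
compendium-style hemoglobin molar extinctions, an oxidized-minus-reduced CCO
difference spectrum, and pure-water absorption at the ten wavelengths used
(690, 830 nm for the hemoglobin-only configuration; 784–894 nm for the
CCO-sensitive set). Forward simulation and inversion share this table, so
conclusions about estimator behavior do not depend on which compendium the
numbers were taken from.

## The single-distance phase-only estimator

Parameters θ = {HbO, Hb, (CCOredox), a, b} are estimated from the phases at
a single (ρ, f) across the configured wavelengths by L-BFGS-B on the
sum-of-squares phase misfit plus the edge-barrier penalty
`R(θ) = Σ α_j u_j²`, `u_j = (θ_j − c_j)/h_j`, where c, h derive from the
physiological bounds (HbO 30–90 µM, Hb 5–40 µM, CCOredox 0–16 µM, a 15–50
cm⁻¹, b 0.5–2). Numerical choices:

* **Scaled coordinates.** The optimizer works in u ∈ [−1, 1]⁵; parameters
  span two orders of magnitude in physical units and the box becomes the
  unit cube, which conditions the quasi-Newton updates.
* **Gradients by complex step.** The whole phase chain is analytic on the
  admissible domain, so derivatives are taken by complex-step perturbation
  (step 1e-30) — exact to machine precision, no subtractive cancellation.
  This is what lets the optimizer run at tight tolerances
  (ftol 1e-16, gtol 1e-10, ≤ 500 iterations) without finite-difference
  noise.
* **Initialization.** Fixed at the range midpoints for every parameter —
  deterministic and unbiased with respect to the admissible box.
* **Degenerate inputs.** Phases outside [0, 2π) are wrapped with a warning;
  non-finite phases are rejected; non-convergence is flagged on the result,
  not raised.

**Choice of α (noise-adaptive edge barrier).** A fixed α cannot serve both
regimes this estimator meets. The scaled phase Jacobian at cohort-mean
optics has singular values spanning ~3.5 orders of magnitude
({4.1e-1, 1.8e-2, 1.3e-2, 1.6e-3, 2.5e-4} at ρ = 2 cm, 110 MHz), so any α
large enough to tame noise along the small modes visibly biases a noiseless
fit, and any α small enough to keep noiseless recovery below 1% leaves noisy
fits effectively unregularized. The shipped default therefore scales the
penalty with the measurement noise: α_j = 3σ², where σ is the phase-noise SD
(user-supplied when the instrument noise is known, otherwise estimated from
the dof-corrected residual of an unregularized first pass when the
wavelength count exceeds the parameter count). The factor 3 is the
Gaussian-matched precision of a uniform prior over the unit box
(variance 1/3). Clean data thus recover the exact inverse-crime solution,
while noisy data get a penalty on the scale of the uncertainty. In the
two-wavelength mode (two phases, four unknowns, σ not estimable) the
unregularized limit applies and the fit returns the data-consistent point
nearest the midpoint initialization in scaled coordinates — the α → 0 limit
of the edge-barrier selection; this is documented loudly because the
two-wavelength problem is under-determined and the selection rule, not the
data, resolves the null space.

## Identifiability limit (what the estimator can and cannot do)

To leading order `k_i ≈ (ω/2v)·sqrt(3µs′/µa)`: a single-frequency,
single-distance phase mostly measures the *ratio* µs′/µa per wavelength.
Absolute scale enters only through the dispersion term `(ω/vµa)²` (~2% here)
and the arctan correction. Consequently the joint scaling
µa → γµa, µs′ → γµs′ — equivalently a coherent scaling of all concentrations
and the scattering amplitude — is nearly invisible. At a phase-noise SD of
0.0035 rad the two smallest Jacobian modes carry noise-limited standard
errors of ≈ 2 and ≈ 14 range-half-widths: per-sample concentration
variability (10% CV) along those directions is unrecoverable, and a
linearized analysis puts the cohort MRE floor near 8% for HbO regardless of
the α configuration. Resolving those modes would need phase noise below
roughly 2e-5 rad — photon budgets far beyond the desk-scale simulations
here. The acceptance suite asserts the published error levels at face value
under the 0.0035 rad protocol; the quantitative targets therefore fail, and
that outcome is the package's documented finding about this noise regime,
not an implementation defect. The consistency properties (closed-form
identities, inverse-crime recovery, slope and unmixing round trips,
MC-vs-diffusion agreement) all pass.

## Monte Carlo engine

Homogeneous cuboid, 10 cm per side; isotropic point source launched into the
lower hemisphere at the center of the top face; detectors are annuli
(default radii 2.0/2.5/3.0/3.5 cm, width 1 mm — a deliberate spatial blur
that buys orders of magnitude of variance at desk-scale budgets).
Henyey–Greenstein scattering with g = 0.85, transport sampling with
µs = µs′/(1 − g); Fresnel reflection/transmission at the top boundary
(n 1.37 → 1.0, including total internal reflection); side and bottom faces
absorb (negligible for ρ ≤ 3.5 cm in a 10 cm cube). Absorption is applied as
a continuous weight `exp(−µa L)` at detection, so the random walk is
independent of µa — the test suite exploits the exact bin-wise equivalence
TPSF(µa) = TPSF(0)·exp(−µa v t). Detection time is total pathlength × n/c0,
binned at 10 ps over a 10 ns window (1000 bins); walks are capped at the
pathlength equivalent of the window. Optional weight roulette
(threshold 1e-4, survival 0.1) exists for workflows that attenuate weights
in flight; it is off by default and must stay off when the µa-equivalence is
relied upon, since roulette decisions would make the walks diverge.

DC/AC/phase are extracted by evaluating `S(f) = Σ w_k exp(−i2πf t_k)Δt` at
the bin centers directly at the modulation frequency: with a 10 ns window
the FFT grid is spaced at 100 MHz, so 110 MHz is deliberately computed
off-grid rather than interpolated. Phase is the lag −arg S, wrapped to
[0, 2π).

Default photon budgets are 2×10⁵–1×10⁶ per (wavelength, sample) — desk
scale. At 2×10⁵ photons and ρ = 2 cm the MC phase agrees with the
closed-form flux phase within 0.05 rad and the mean time of flight with the
semi-infinite diffusion TPSF within a few percent.

## Synthetic cohort

Thirty samples per cohort. Concentrations ~ Normal(mean, 0.1·mean),
truncated at zero (with means 60/25/8.5 µM the truncation is 5.9+ SDs away
and never fires in practice; a 1000-draw test confirms): HbO 60, Hb 25,
CCOredox 8.5 µM. Scattering a ~ Normal(24.2, 1%), b ~ Normal(1.611, 1%).
Water fraction fixed at 0.75. The two-wavelength (hemoglobin-only) cohort
sets CCOredox = 0: that configuration models HbO, Hb and water only, and its
inversion has no CCO term. The surrogate forward adds Gaussian phase noise
(default SD 0.0035 rad ≈ 0.2°, a typical instrument-grade phase precision)
to the closed-form phases; amplitudes stay noiseless.

What the generator does *not* emulate: layered or heterogeneous tissue,
instrument drift or amplitude noise, wavelength-dependent coupling,
boundary-curvature effects, or chromophores beyond the four modeled.
Passing tests therefore demonstrate estimator behavior under an idealized,
internally consistent optical model — an inverse-crime setting by design for
the surrogate route, with the Monte Carlo route as the model-mismatch check.

## Evaluation

MAE = mean |est − truth| (physical units) and MRE = mean(|est − truth|/truth)
× 100, computed per chromophore and per method: the four-distance slope
method versus the single-distance fit applied independently at each
separation (SD1–SD4). The experiment runner persists the per-sample truth
table beside every set of estimates and is bit-reproducible under a fixed
seed for both forward routes.

## Known limitations

* The slope→optics conversion uses the infinite-medium relations consistent
  with the flux-phase model; semi-infinite slope corrections are out of
  scope.
* The two-feature (amplitude + phase) variant with a gain parameter is
  deliberately not implemented; the cost interface leaves a hook for it.
* The estimator assumes hemoglobin-dominant tissue; the spectral
  parameterization has no lipid or melanin terms.
* Desk-scale MC budgets make channels beyond ~3 cm noisy; the runner reports
  empty channels as NaN with a logged warning rather than failing.
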