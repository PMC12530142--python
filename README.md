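# fdphase

Single-distance, phase-only frequency-domain near-infrared spectroscopy
(FD-NIRS) for absolute quantification of tissue chromophores — oxy- and
deoxy-hemoglobin (HbO, Hb) and the differential redox-state concentration of
cytochrome c oxidase (CCOredox = oxidized − reduced, a marker of
mitochondrial metabolism) — together with the simulation machinery needed to
study such an inversion *in silico*: a time-resolved Monte Carlo photon
transport engine, a closed-form photon-density-wave forward model, and the
conventional multidistance slope method as a baseline.

The package is for biophotonics researchers who want to evaluate
single-separation, single-frequency phase-only reconstruction — a geometry
that removes the multidistance hardware requirement of conventional FD-NIRS —
under controlled synthetic conditions.

## Model

Intensity-modulated light (modulation frequency `f`, angular frequency
`ω = 2πf`) in a highly scattering medium forms a photon-density wave governed
by the diffusion approximation. With absorption `µa`, reduced scattering
`µs′`, diffusion coefficient `D = 1/(3(µa + µs′))` and in-medium light speed
`v`, the complex wavevector has components

    k_r = sqrt( (µa/2D) (sqrt(1 + (ω/vµa)²) + 1) )
    k_i = sqrt( (µa/2D) (sqrt(1 + (ω/vµa)²) − 1) )

and the detected-flux phase lag at source-detector separation ρ is

    Φ(ρ) = k_i ρ − arctan( k_i ρ / (1 + k_r ρ) ).

Optical spectra are parameterized by a handful of wavelength-independent
physiological quantities: Beer–Lambert absorption
`µa(λ) = Σ_i ε_i(λ) C_i + f_w µa,water(λ)` over chromophores
i ∈ {HbO, Hb, CCOredox} with a fixed 75% water fraction, and power-law
scattering `µs′(λ) = a (λ/λ0)^(−b)` (λ0 = 500 nm).

**FD1SD_phase**, the core estimator, recovers θ = {HbO, Hb, (CCOredox), a, b}
from the phases at one ρ and one modulation frequency (110 MHz) across either
two (690/830 nm) or eight (784–894 nm) wavelengths, by bounded L-BFGS-B
minimization of

    E(θ) = Σ_λ [Φ_model(λ; θ) − Φ_meas(λ)]² + R(θ),
    R(θ) = Σ_j α_j ((θ_j − c_j)/h_j)²,

where (c_j, h_j) are the midpoint and half-width of each parameter's
physiological range (HbO 30–90 µM, Hb 5–40 µM, CCOredox 0–16 µM, a 15–50,
b 0.5–2) — an "edge-barrier" penalty that is zero mid-range and α_j exactly
on a bound. The default α is noise-adaptive (`3·σ²` for phase-noise SD σ, in
range-normalized coordinates), so clean data are fit essentially
unregularized; see `docs/methods.md`.

## Worked example

```sh
python examples/single_distance_inversion.py
```

prints

```
truth:     HbO=66.00  Hb=22.00  CCOredox=9.00  a=24.00  b=1.600
clean fit: HbO=66.00  Hb=22.00  CCOredox=9.00  a=24.00  b=1.600  (residual 4.30e-18 rad^2)
noisy fit: HbO=63.20  Hb=21.65  CCOredox=10.08  a=22.74  b=1.479
```

Eight noiseless phases at a single 2 cm separation identify all five
parameters exactly (the residual is at machine precision). Adding 0.0035 rad
of Gaussian phase noise leaves a near-degenerate joint-scaling direction of
(concentrations, scattering amplitude) unresolved, so the noisy estimates
drift by a few percent — the central trade-off this package lets you
quantify.

Other examples: `forward_phase_model.py` (phase spectra versus separation),
`monte_carlo_forward.py` (MC vs diffusion phase), `method_comparison.py`
(cohort-level slope-method vs single-distance comparison). A thin CLI wraps
the same workflow: `fdphase report --mode eight --n-samples 30 --seed 1
--out out/`.

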