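# Methods

This note records the models implemented in `coralight`, the defaults and
their rationale, what the synthetic-data generators do and do not emulate,
and the numerical choices that shape the results.

## Units and conventions

Lengths are millimetres inside the optics code and micrometres in the
imaging/physiology code (converted at I/O boundaries); wavelengths nm;
time ns with c = 299.792458 mm/ns; concentrations µmol L⁻¹; the O2
diffusion coefficient is supplied in cm² s⁻¹ (default 2.255×10⁻⁵ cm² s⁻¹,
for 25 °C seawater at salinity 30) and converted internally; fluxes are
reported in nmol O2 cm⁻² s⁻¹. Image stacks are (z, y, x) with z
increasing into the sample; STL files are written in micrometres (STL
itself carries no units).

## Monte Carlo photon transport

Standard weighted-packet random walk: step lengths from the extinction
coefficient, absorption by albedo weighting (lower variance than
termination sampling at the high-absorption tissue settings), deflection
angles from the Henyey–Greenstein distribution, uniform azimuth,
unpolarized Fresnel coefficients with Snell refraction at index steps, and
Russian roulette below weight 10⁻⁴ (survival probability 0.1). Fluence
uses the track-length estimator (deposited path per volume), which stays
unbiased in non-absorbing media and equals the relative fluence rate
E0/E_d for a normally incident unit beam. Time of flight accumulates
n·s/c per sub-step; the time-binned fluence integrates exactly to the
steady-state profile (the estimator advances the clock within long
ballistic segments, so clear layers gate correctly).

Two domains share the physics: an infinite layered slab (exact boundary
geometry; used for all quantitative fits) and a laterally periodic voxel
grid (label array + material map; Fresnel on axis-aligned faces). Lateral
periodicity makes a uniform voxel slab exactly equivalent to the layered
one — verified in tests — and represents an array of corallites without
side-loss bookkeeping. Pencil beam and plane wave coincide for laterally
averaged slab quantities.

Validation invariants (all in the test suite): T = 1 for a matched clear
slab (exact); Beer–Lambert T = e^(−µ_a L) within 3 Monte Carlo standard
errors; T+R+A = 1 to 10⁻³ (roulette is the only non-conservation);
agreement with the diffusive-slab closed form within 10% for
L/l_t ∈ [5, 20]; reciprocity of a flipped two-layer slab; HG sample mean
equal to g within 3 SE; Fresnel normal-incidence reflectance 0.04 for
n 1.0→1.5.

## Material presets

* **Skeleton** (PEGDA + cellulose nanocrystals): near-isotropic scattering
  with scattering mean free path 3 mm; since g = 0 the transport mean free
  path coincides, so µ_s = 1/3 mm⁻¹, g = 0. Index n = 1.47 (dense PEGDA),
  residual µ_a = 0.003 mm⁻¹. The equality of scattering and transport mean
  free paths under near-isotropic scattering is an interpretation choice,
  stated here deliberately.
* **Tissue** (GelMA + microalgae): absorption scales with algal density as
  15 mm⁻¹ per 10⁹ cells/mL; scattering is weak and strongly
  forward-peaked. Only the forward-scattering character is constrained by
  measurement, so µ_s = 10 mm⁻¹ with g = 0.9 (transport mean free path
  1 mm) is this package's documented choice: it produces a forward cone
  after ~1 mm of tissue while keeping the sample in the Beer–Lambert
  regime for thin sections. n = 1.37, the lower edge of the measured
  Brewster window.
* **GelMA reference**: the same matrix without scatterers (µ_s = 0),
  optionally loaded with the same absorber density — the comparison slab
  for fluence-enhancement studies (run at 5×10⁶ cells/mL, the density of
  the fluence profiling experiments).

The fluence-enhancement figure (two-layer vs clear slab at 750 µm) is a
consistency check of this preset family, not a parameter-free prediction:
with the presets above the simulated ratio is ≈2.0, comfortably above the
1.5-fold enhancement the design targets.

## Extrapolation-length fitting

`P(µ) = µ(z_e + µ)/(z_e/2 + 1/3)` is fitted with a free scale (the
estimate is invariant under intensity rescaling; tested). Two angular cuts
are applied: the bin around the ballistic axis is excluded (any residual
unscattered beam concentrates there), and angles beyond 80° are excluded —
grazing exit is where the diffusion boundary model deviates most from
exact transport and where goniometer arms physically cannot reach. Fits
are weighted by per-point uncertainties when present; Monte Carlo scans
carry Poisson-scale uncertainties per solid-angle bin.

Under this convention, a matched-boundary diffusive slab yields z_e ≈
0.61–0.63 (between the diffusion value 2/3 and below the exact Milne value
0.7104 — the residual transport-vs-diffusion shape difference inside
80° pulls the weighted fit slightly low). A skeleton-index slab
(n = 1.47) immersed in water (relative index 1.105) yields z_e ≈ 1.26–1.32.
The hydrated measurement geometry matters: the same slab against air
(relative index 1.47) would produce a near-Lambertian external
distribution and an effective z_e above 2 — hydrogel optics must be
measured wet, and the package's headline z_e computation does so.

## Diffusive-slab transmission and the iterative fit

The default `diffusion_transmission` is the extrapolated-boundary
diffusive-slab solution (source at depth l_t, zero-density planes at
−z_e·l_t and L + z_e·l_t, diffusive absorption length √(l_a·l_t/3)),
with an overflow-safe asymptotic branch deep in absorption. An
`as_printed` mode evaluates a literal transcription of the published
closed form, which carries a 1/l_a prefactor and a squared sinh in the
numerator; that expression is dimensionally inconsistent and is retained
for transparency only — the fits never use it. `fit_diffusion` estimates
z_e from the angular scan, then fits (l_a, l_t) in log-space with bounds,
repeating from the previous optimum until successive estimates change by
<1% (cap 50): the stability iteration converges in two passes on clean
data and flags non-convergence rather than raising.

## Brewster refractometry

`make_brewster_scan` generates p-polarized Fresnel reflectance (the one
place polarization matters; the MC itself is unpolarized);
`find_brewster` locates the minimum by three-point parabolic
interpolation, refusing scans whose minimum sits on an edge.
`n = n_ambient·tan θ_B` maps 54.0°→1.376 and 55.0°→1.428, spanning the
1.37–1.40 printed-tissue window at measurement precision.

## Image chain

Median denoising uses reflected edges. Per-slice multilevel Otsu (default
3 classes, configurable) takes the top class as foreground; slices whose
class separation is on the noise scale (background-only slices) inherit
the nearest valid slice's threshold, generalizing the constant-slice
fallback. On a two-level phantom the matching choice is 2 classes; with 3
classes the top threshold necessarily splits the single foreground mode,
which is a property of Otsu's objective, not a bug — the provenance log
records every threshold used.

Surface extraction runs marching cubes at level 0.5 on a lightly
Gaussian-smoothed (σ = 1 voxel) copy of the binary field; smoothing
suppresses the staircase bias of binary isosurfaces (digital-ball area
then lands within 3% of 4πr²), and structures thinner than the kernel
fall back to the raw isosurface. Faces are oriented so the
divergence-theorem volume is positive. Hole filling fan-triangulates
boundary loops up to a size cap and reports larger holes untouched.

Slicing casts a vertical ray through each (jittered) pixel centre and
accumulates orientation-signed crossings; a running winding sum > 0 marks
the interior. Signed counting is essential: plain even–odd pairing breaks
on marching-cubes meshes because a ray through a shared-edge projection
registers duplicate hits (this failure mode was observed and is why the
parity is signed). Layer count is ⌈z-extent / layer thickness⌉; the
mask-stack volume matches the mesh volume within 3% on the ball phantom
and 5% through the full noisy corallite chain.

Particle segmentation: intensity window (defaults 229–4095 on the 12-bit
scale) → minimum-size filter at clean_factor × a 27-voxel base (the
"cleaning factor" of confocal practice, interpreted as size filtering) →
hole filling → morphological closing of radius smooth_factor (touching
particles within the closing scale merge; documented and tested) →
26-connected labelling. Surface areas come from a per-particle smoothed
isosurface so sphericity ψ = π^(1/3)(6V)^(2/3)/A is accurate to ~3% at
the phantom's 30–50 µm diameters.

## Physiology

The DBL window for Fick's-law flux is the maximal-R² contiguous window
anchored at the surface-most point (the gradient region is by definition
adjacent to the surface; unanchored selection can latch onto the flat bulk
region, which is also perfectly linear). A window failing R² ≥ 0.95
raises with the best window found; a flat profile is perfectly linear
with zero slope and returns J = 0. Sign convention: positive J = O2
leaving the surface; the generator and fitter share `J = −D·dC/dz` on the
depth axis, and both flux directions are tested.

The light–dark-shift rate is the negative initial slope over a 1 s window
(chosen from the stated <0.2 s sensor response) after darkening.

PI curves use the saturating exponential without photoinhibition — the
standard Webb-type referent for "exponential" PI fits; at E = Ek the
modelled rate is (1−1/e)·Pmax.

Growth fits are logistic — the paper behind this package says only "curve
fits", and logistic is the standard saturating-growth default — performed
on log densities, consistent with multiplicative replicate scatter.
Confidence bands propagate the parameter covariance by the delta method
on the log scale; prediction bands add the residual variance and use
t-quantiles. Delta-method bands were chosen over bootstrap for
determinism; coverage of the 95% prediction band measures 95% ± 4% over
200 simulated datasets. Default calibration: N0 = 10⁶ cells/mL
(inoculation density), K = 9×10⁸, r = 0.8 day⁻¹ — the growth conditions
under which density exceeds 8×10⁸ cells/mL by day 12, matching the
culture experiment this emulates; sampling days {0, 3, 6, 10, 12}.

## What the phantoms do and do not emulate

Phantoms reproduce the *statistical structure* the estimators assume:
two-level OCT-like volumes with multiplicative speckle-scale noise,
diffusion-model transmission series with multiplicative Gaussian noise,
exact Fresnel Brewster scans, linear-DBL O2 profiles with additive noise,
log-normal replicate scatter on counts. They do not model OCT speckle
physics, confocal point-spread functions, instrument drift, sample
roughness or pigment spectra. Passing round trips therefore demonstrates
estimator correctness and calibration under the stated noise models — not
robustness to every artefact of real instruments. Generators with
noise_rel = 0 return analytically exact values of their stated models, and
every generator is byte-identical under a fixed seed; ground-truth records
ride along with each dataset and are never read by fitting code.

The corallite phantom's cup is a semi-ellipsoidal bowl of 1 mm diameter
and 1 mm depth (a hemisphere of that diameter would be only 0.5 mm deep)
with eight 200 µm × 1 mm tentacle cylinders inset on the rim so the xy
footprint stays at the cup diameter.

## Problem sizes and determinism

Default budgets: 10⁵ photons for exploratory runs and unit tests
(statistical tolerances are set at 3 MC standard errors for that size),
2–4×10⁵ photons × 5 seeds for the headline z_e computation, 10⁵–2×10⁵ × 3
seeds for fluence ratios; each choice keeps every check a desk-scale
computation while leaving its tolerance dominated by model error, not
sampling noise. All randomness flows from explicit integer seeds (numba's
per-kernel `np.random.seed`; generator `default_rng`), making every test
and the acceptance script reproducible run-to-run.

## Known limitations

No polarization inside the MC (only the Brewster generator is
polarization-aware), no fluorescence, no tetrahedral meshes, no GPU. The
voxel MC resolves index mismatches on axis-aligned faces only, so curved
interfaces acquire a staircase approximation at coarse voxel sizes. The
`as_printed` transmission mode is deliberately not fitted. Growth bands
assume log-normal replicate scatter; heavy-tailed count noise would
under-cover. The angular-fit convention (weighted, 1°–80°) is part of the
z_e definition here; fitting unweighted or to wider angles shifts the
estimate by ~10% and should be stated alongside any reported value.
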