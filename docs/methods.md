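# Methods

## The FCS model

A transcription factor in the nucleus is modeled as a molecule that
diffuses freely with coefficient `D` and exchanges with two classes of
immobile chromatin sites. Detection is a 3-D Gaussian observation volume
with radial e⁻² waist `w_r` and axial waist `w_z = ω·w_r`. The normalized
autocorrelation of the detected intensity is

    G(τ) = 1/(2^{3/2} N) [ f_D (1 + τ/τ_D)^{-1} (1 + τ/(ω² τ_D))^{-1/2}
                           + f_short e^{−τ/τ_short} + f_long e^{−τ/τ_long} ]

with `τ_D = w_r²/(4D)` and fractions on the simplex. The model's
assumptions, and hence the package's:

- bound molecules are strictly immobile (chromatin sites are fixed), so
  binding contributes pure exponentials with time constants `1/k_off`;
- the two binding classes occupy distinct temporal windows,
  `τ_D < τ_short < τ_long`;
- no photophysics: photobleaching, triplet blinking and detector
  afterpulsing are outside the model, and the simulator deliberately does
  not produce them.

### Amplitude conventions

The simulator defines `N` over the e⁻² effective volume
`V_eff = π^{3/2} w_r² w_z`. With that definition the physical amplitude of
a pure-diffusion ACF is `G(0) = 1/N_sim`, whereas the fitted model reports
`G(0) = 1/(2^{3/2} N_fit)` — the two `N`s differ by the fixed geometric
factor `2^{3/2} ≈ 2.83` (equivalently, `N_fit` counts molecules in the
smaller volume `(π/2)^{3/2} w_r² w_z`). Mean detected count rate obeys
`⟨rate⟩ = ε·N_sim/2^{3/2} + background`, which follows from averaging the
Gaussian profile over uniformly distributed emitters; this closed form is
asserted by the tests. Recovery comparisons are therefore made on `τ_D`,
residence times and fractions — never on `N` across the two conventions.

## The trace simulator

Particles perform Brownian steps (per-axis variance `2·D·Δ` with `Δ` the
bin width) in a periodic cube and emit photons as per-bin Poisson draws
with rate `ε·Σᵢ w(rᵢ) + background`, `w` the Gaussian detection profile.

**Box size.** The cube half-extent is `box_margin × w_z` per axis
(default margin 4). The box must be large not only against the detection
profile (which decays as e⁻² per waist) but against a subtler artifact:
a periodic box holds an exactly conserved number of particles, which
suppresses the long-lag correlation relative to the open-system model
(canonical vs grand-canonical number fluctuations, relative magnitude
~`V_eff/V_box`). With the default cube this residual is below the
statistical noise of the recovery experiments; with a box shrunk to a few
radial waists laterally it biases fitted `τ_D` by several percent.

**Binding kinetics.** Free→bound and bound→free transitions are first-order
with the configured `k_on`/`k_off`. Each particle's state timeline is
sampled event-driven — exact exponential waiting times, the class chosen
with probability proportional to its `k_on`, the initial state from the
steady-state occupancy — and quantized to the bin grid; `simulate_trace`
requires `rate × bin_width ≤ 0.1` so quantization error stays negligible.
This is statistically exact for the same Markov model as per-step
switching and an order of magnitude faster. Steady-state fractions follow
detailed balance, `f_j = (k_on,j/k_off,j)/(1 + Σ_k k_on,k/k_off,k)`.

The single-particle trajectory math runs in float32 (position scale ~μm,
step scale ~10 nm; rounding is far below thermal noise); per-bin photon
expectations accumulate in float64.

## Correlator

Both estimators use the symmetric (time-matched) normalization
`G(k) = ⟨F_t F_{t+k}⟩ / (⟨F⟩_left ⟨F⟩_right) − 1`, which removes the
finite-trace bias of a global-mean normalization. The multi-tau scheme
uses m = 16 linear channels per stage and coarsens the trace by 2 between
stages; each stage's values are exactly the direct estimator applied to
the coarsened trace, which is how the tests verify the scheme (a
coarsened-stage estimate cannot equal the full-resolution single-bin
estimator identically, because bin averaging is lossy). The zero-lag
channel is shot-noise dominated and never reported. Fits use lags up to
one tenth of the trace duration; beyond that the estimator variance and
residual normalization bias grow quickly.

## Fitting

Weighted nonlinear least squares (`scipy.optimize.least_squares`, TRF)
with:

- fractions parameterized by stick-breaking on the simplex (exact
  constraint, no penalty terms);
- characteristic times in log space;
- `ω` fixed from calibration (default 5) — it is degenerate with `τ_D`
  and is never fitted;
- a 3×3 multi-start grid over `τ_short ∈ {10⁻³..10⁻¹} s`,
  `τ_long ∈ {10⁻¹..10} s`; best residual sum of squares wins, ties go to
  the smaller `τ_long`;
- residence times relabeled after optimization so `τ_short < τ_long`
  (the two exponentials are exchangeable);
- residual weights `1/SD(τ)` when the curve carries per-lag standard
  deviations, else uniform;
- standard errors from the curvature at the optimum, delta method for the
  simplex-derived fractions and log-parameterized times.

Model variants (`components`) allow pure-diffusion or
diffusion + single-exponential fits for data generated without one of the
binding classes. Non-convergence across all restarts yields a flagged
result, not an exception.

**Recovery noise model.** The parameter-recovery experiments corrupt model
curves with Gaussian noise of SD `0.05·G(τ)` — 5% of the amplitude at
τ→0, decaying with the curve. This heteroscedastic profile matches the
fitter's 1/SD weighting (a correctly specified WLS, recovering the
long-lived component essentially unbiased) and mirrors how the dispersion
of averaged experimental ACFs scales with the curve in its decay region.
Under a flat noise profile of the same amplitude the estimator acquires
the small right-skew typical of positive scale parameters in nonlinear
least squares (~1% on f_long, ~10% on the mean of τ_long at this noise
level); that skew is intrinsic, not an optimizer defect.

## Morphometry

Median filter (3-D ball, radius 1 voxel) → Rudin–Osher–Fatemi
total-variation denoising (Chambolle projection; weight defaults to
0.1 × the intensity range, 50 iterations) → Otsu global threshold →
26-connected components → slice-wise hole filling → size gate
(defaults 50–4000 μm³).

Volume is voxel count × physical voxel volume. Surface area comes from a
marching-cubes iso-surface at level 0.5 with anisotropic voxel spacing in
physical coordinates; the binary label is first smoothed with a Gaussian
of width one coarsest-axis voxel, because a raw binary iso-surface
overestimates a sphere's area by ~12% (and voxel-face counting by 6/π),
which would corrupt the sphericity `Ψ = π^{1/3}(6V)^{2/3}/A`. The
smoothing introduces a small curvature bias, so a well-resolved sphere
measures `Ψ = 1.00 ± 0.02` (the mesh tolerance); coarsely sampled spheres
(radius ≲ 10 voxels along z) can exceed 1 by up to ~0.03. Labels touching
the image border are flagged as truncated and excluded from group
statistics. Anisotropic z-spacing is handled by physical-coordinate
meshing, never by resampling the image.

## Synthetic nuclei

Solid ellipsoids, optionally perturbed radially by a seed-deterministic
combination of degree-2/3 real spherical harmonics (normalized so the
relative amplitude is exact). Voxelization uses 2× supersampled occupancy
and a random sub-voxel center offset: grid-aligned spheres carry a
systematic parity error of up to ~1% in voxelized volume, while random
offsets make the error zero-mean across a population — real nuclei are
never grid-aligned. The solid is blurred with a Gaussian PSF (default
σ = 0.3 μm) and corrupted with Poisson (default) or Gaussian noise.
Ground truth is closed-form for ellipsoids (exact Legendre elliptic-
integral surface area) and a dense surface triangulation (400×800
parameter grid) for perturbed shapes.

What the generator does **not** emulate: intensity inhomogeneity inside
the nucleus (chromocenters, nucleoli), touching nuclei, anisotropic PSF
side lobes, depth-dependent attenuation, and cell movement. Passing tests
therefore demonstrate correctness of the measurement chain on well-behaved
single nuclei, not robustness to crowded or low-quality stacks.

## Group statistics

`summarize_groups` reports median ± bootstrap SE (morphometry convention)
or mean ± bootstrap SE (FCS convention). The two-group comparison uses
`z = |Δmed|/√(σ²₁+σ²₂)` with `σ²` the bootstrap variance (default 1000
resamples) of each group's median (the statistic under comparison — the
coherent plug-in), and `p = 2(1 − Φ(z))`. Default α is 0.05 for
morphometry and 0.01 for FCS comparisons. Volume ratios translate to
radius changes as `((V_t/V_ref)^{1/3} − 1)·100` %, assuming volume scales
with the radius cubed. Mixed-model analyses with multi-group post-hoc
corrections are intentionally out of scope; the pipeline emits tidy
per-cell tables suitable for external mixed-model software.

## Problem sizes used in tests and the acceptance script

Chosen as the package's own desk-scale defaults:

- end-to-end diffusion recovery: 10 traces of 5 s at 0.1 ms bins
  (D = 10 μm²/s, w_r = 0.25 μm, ω = 3, N = 2 → `τ_D` = 1.56 ms);
- end-to-end binding recovery: 10 traces of 60 s at 0.5 ms bins with one
  site class at `k_on = k_off = 1/s` (a residence time of 1 s needs ≳50
  binding events per trace for a stable exponential tail; 40 s traces are
  visibly unstable);
- fitter recovery: 100 curves, 160 log-spaced lags over 10 μs–10 s;
- median-test calibration: 500 null replicates of n = 50 with 500
  bootstrap resamples;
- two-condition pipeline checks: 12 cells per condition, 10 repetitions;
- morphometry: spheres of 4.5–5 μm radius at 0.25×0.25×0.5 μm (0.15/0.3
  for the high-resolution sphericity check) voxels.

Every stochastic stage derives its seed by hashing (master seed, stage
name, item index), so outputs are bit-identical across reruns and
independent of execution order.

## Known limitations

- The ACF of the simulation matches the two-binding-population model only
  in the time-scale-separated regime the model assumes; with binding rates
  comparable to `1/τ_D` the exponential-term amplitudes deviate from the
  steady-state fractions.
- Absolute fitted residence times depend on the (fixed) calibration `ω`
  and on acquisition settings; they are comparable within a consistently
  processed dataset, not across setups.
- Segmentation assumes one intensity class of nuclei on a darker
  background; touching nuclei are not split.
- The median test is asymptotic (normal approximation); at very small n
  (< ~10 per group) its type-I error is only approximately calibrated.
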