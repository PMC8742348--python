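# nucleodyn

Quantitative analysis of transcription-factor dynamics and nuclear shape in
live embryonic stem cells, from two complementary read-outs:

1. **Single-point FCS** — fluorescence intensity fluctuations recorded in a
   femtoliter confocal volume are autocorrelated and fitted with a
   diffusion + two-binding-population model to recover the fractions of a
   transcription factor (e.g. OCT4) that diffuse freely or stay bound to
   short- and long-lived chromatin targets, together with the residence
   times of those interactions.
2. **3-D nuclear morphometry** — confocal z-stacks of nuclei are denoised
   (median + total-variation filters), segmented by automatic global
   thresholding, and quantified per nucleus as volume, surface area and
   sphericity.

Group differences are assessed with a bootstrap median test, and volume
changes are translated into equivalent radius changes through the
cube-root rule. A synthetic-data module generates photon traces, model
curves and voxelized nuclei with known ground truth, so the entire
pipeline is testable without any microscope data.

## The model

The normalized autocorrelation of the photon trace, G(τ) = ⟨δF(t)δF(t+τ)⟩/⟨F⟩²,
is described by

```
G(τ) = 1/(2^{3/2} N) [ f_D (1 + τ/τ_D)^{-1} (1 + τ/(ω² τ_D))^{-1/2}
                       + f_short exp(−τ/τ_short)
                       + f_long  exp(−τ/τ_long) ]
```

where `N` is the mean number of fluorescent molecules in the confocal
volume, `τ_D` the characteristic diffusion time through a 3-D Gaussian
observation volume with axial/radial waist ratio `ω`, and
`f_D + f_short + f_long = 1` are the population fractions of freely
diffusing, short-lived bound and long-lived bound molecules with residence
times `τ_short < τ_long`. The reciprocal of a residence time is the
dissociation rate `k_off`.

Nuclear shape is summarized by the sphericity
`Ψ = π^{1/3} (6V)^{2/3} / A`, which equals 1 for a sphere and decreases as
the nucleus deforms. Two group medians are compared with

```
p = 2 [ 1 − F( |med(g1) − med(g2)| / sqrt(σ²(g1) + σ²(g2)) ) ]
```

where `F` is the standard normal CDF and `σ²` the bootstrap variance of
each group's median.

## Worked example

```python
import numpy as np
from nucleodyn import (
    TraceSimConfig, simulate_trace, autocorrelate, AcfModelFitter,
    CorrelationCurve,
)

cfg = TraceSimConfig(
    diffusion_coefficient=10.0,   # um^2/s
    w_r=0.25, omega=3.0,          # calibrated observation volume
    n_molecules=2.0, brightness=1e5,
    bin_width=5e-4, duration=60.0,
    binding_classes=((1.0, 1.0),),  # one site class, k_on = k_off = 1/s
    seed=300,
)
trace, truth = simulate_trace(cfg)
curve = autocorrelate(trace, scheme="multi_tau")
keep = curve.lags <= trace.duration / 10
fit = AcfModelFitter(omega=3.0, components=("diffusion", "long")).fit(
    CorrelationCurve(lags=curve.lags[keep], g=curve.g[keep])
)
print(f"tau_long = {fit.params_.tau_long:.2f} s  (truth 1.00 s)")
print(f"f_long   = {fit.params_.f_long:.2f}     (truth {truth.f_long:.2f})")
```

Output:

```
tau_long = 0.59 s  (truth 1.00 s)
f_long   = 0.47     (truth 0.50)
```

The fitted residence time of the planted binding class (1/k_off = 1 s) and
its steady-state bound fraction (k_on/k_off / (1 + k_on/k_off) = 0.5) are
recovered from nothing but the simulated photon counts. A single 60-second
trace holds only ~60 residence times of this slow class, so individual
estimates of `tau_long` scatter by roughly ±0.3 s; averaged over 10 seeds
the recovery is unbiased (the test suite and the acceptance script do
exactly that).

The morphometry side works the same way from synthetic stacks:

```python
from nucleodyn import NucleusShapeSpec, generate_nucleus_image, NucleusSegmenter

image, truth = generate_nucleus_image(
    NucleusShapeSpec(semi_axes=(5, 5, 5), voxel_size=(0.15, 0.15, 0.3))
)
rec = NucleusSegmenter().measure(image)[0]
print(f"volume {rec.volume:.0f} um^3 (truth {truth.volume:.0f}), "
      f"sphericity {rec.sphericity:.3f}")
# volume 523 um^3 (truth 524), sphericity 1.007
```

## Command line

```bash
nucleodyn simulate trace   --config trace.json   --out out/ --seed 1
nucleodyn simulate acf     --config params.json  --out out/ --seed 1
nucleodyn simulate nucleus --config shape.json   --out out/ --seed 1
nucleodyn fcs run          --config fcs.json     --out run/ --seed 1
nucleodyn morpho run       --config morpho.json  --out run/ --seed 1
```

Configs are JSON/YAML files holding the fields of `TraceSimConfig`,
`FcsParams`, `NucleusShapeSpec` or `RunConfig`; pipeline runs write
per-cell/per-nucleus CSV tables, a comparisons CSV and a `run_info.json`
provenance record, all bit-reproducible under the same seed.

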