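# fiborient

Quantitative analysis of fiber organization in grayscale micrographs from
the statistics of intensity gradients.

Fibrous tissues — the collagen lamellae of the corneal stroma imaged by
second-harmonic generation (SHG) microscopy are the motivating case — owe
their mechanical and optical properties to how well their fibers are
aligned. `fiborient` measures that organization directly from a
single-channel image: every bright elongated fiber produces intensity
gradients perpendicular to its axis, so the distribution of gradient
orientations is a fingerprint of the fiber architecture. The package
computes that distribution, fits it to a compact parametric model, and
reports scalar order metrics that can be compared across specimens,
species, or time points (e.g. wound healing, cross-linking treatment).

## Method

1. **Normalize** the image so its maximum intensity is 1 (thresholds become
   comparable across acquisitions).
2. **Gradient** at resolution *R*: the centered unit difference of
   *R* × *R* boxcar means — the intensity change averaged over the stencil.
   *R* = 1 is the ordinary centered difference; larger *R* suppresses the
   exact-tie artifacts of integer photon-count noise.
3. **Threshold** at *T* (absolute, or a fraction of the maximum gradient
   magnitude): vectors weaker than *T* carry noise, not structure.
4. **Fold and bin**: gradient directions θ ∈ (−180°, 180°] are folded onto
   the orientation half-plane (0°, 180°] (a vector and its antiparallel
   partner mark the same fiber edge) and binned at width *B* into a
   unit-area probability density function (PDF).
5. **Model fit**: the PDF is fitted by bounded least squares to

   PDF(θ) = Σₖ aₖ · exp(−(θ − bₖ)² / (2 cₖ²)) + d

   — *k* Gaussians over a common pedestal *d*. Each Gaussian is one fiber
   family: *bₖ* its dominant orientation, *cₖ* its angular spread, *aₖ* its
   height above the pedestal; *d* absorbs the structureless (noise)
   fraction. The model order *k* is the least one whose R² reaches the
   maximum attained over *k* = 1…k_max.

Derived metrics: Gaussian areas *aₖcₖ√(2π)*, pedestal area *d*·180°, their
ratio (structure vs. noise), pairwise peak separations |bⱼ − bᵢ|, and the
composite peak-height-to-width ratio (a₁ + d)/c₁ used for longitudinal
tracking.

Because suitable micrographs are rarely public, the package ships a phantom
generator (`fiborient.phantoms`) producing fiber gratings with known
orientation, waviness and photon-count noise, so the whole pipeline is
testable against analytic ground truth.

## Worked example

```python
import fiborient as fo

spec = fo.PhantomSpec(
    families=({"orientation": 60.0, "period": 12.0, "waviness": 18.0},),
    noise_model={"kind": "poisson", "peak": 25},
    background=0.15,
    seed=1,
)
img = fo.make_fiber_image(spec)
res = fo.analyze_image(img, R=2, t_fraction=0.10, B=5)
```

prints (via `res.model` and `res.metrics`):

```
selected k = 1, R^2 = 0.996
a = 0.0152 deg^-1, b = 149.4 deg, c = 22.5 deg, d = 0.00078 deg^-1
Gaussian area = 0.860
pedestal area = 0.140
Gaussian/pedestal ratio = 6.15
```

The wavy fibers drawn at 60° produce gradients at 150°; the fitted center
b = 149.4° recovers that within half a degree. The 18° waviness appears as
the angular spread c = 22.5°, and 86% of the orientation mass is organized
(Gaussian) versus 14% structureless pedestal from the photon noise. A
crossed phantom with families at 30° and 120° (lamella-like domains) yields
`k = 2, centers = [30.2, 120.5]`, peak separation 90.3°.

The same pipeline is available from the shell:

```sh
fiborient simulate --spec spec.json --out phantoms/
fiborient analyze --input phantoms/phantom_000_seed1.tif \
    --resolution 2 --t-fraction 0.10 --binning 5 --out results/
fiborient analyze --input t0.tif --input t1.tif --input t2.tif \
    --threshold 0.05 --series --out series/   # longitudinal panel, k = 1
```

`analyze` writes, per image, the orientation map (PNG + CSV), the binned
PDF (CSV + metadata), the fitted model (JSON) and the metrics (CSV), plus a
run log; `--series` adds a time-point panel with R², Gaussian height/width,
the composite ratio, and an R² ≥ 0.75 quality flag.

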