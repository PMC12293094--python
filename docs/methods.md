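# Methods

## Model

An elongated bright fiber produces intensity gradients perpendicular to its
axis on both flanks. After folding directions onto the orientation
half-plane (0°, 180°], the per-degree probability density of gradient
orientations is modelled as

PDF(θ) = Σₖ aₖ · exp(−(θ − bₖ)² / (2 cₖ²)) + d

with one Gaussian per fiber family and a common pedestal. The model
assumes (i) each family has a single dominant orientation with roughly
symmetric angular scatter, (ii) families are few (k ≤ 3) and reasonably
separated, and (iii) unstructured image content contributes an
orientation-uniform background, absorbed by *d*. The Gaussians are ordinary
(non-circular) functions of θ; periodicity is handled by circularly
shifting the angular axis before fitting, not by wrapping the model (see
"Shifting", below).

## Gradient operator

The gradient at resolution R is the centered unit difference of R × R
boxcar means:

    S(i, j)  = mean of I over the R × R window anchored at (i, j)
    gx(i, j) = (S(i, j+1) − S(i, j−1)) / 2
    gy(i, j) = (S(i+1, j) − S(i−1, j)) / 2

Two properties motivated this choice over one-sided span differences:

* **Exact averaging identity.** The boxcar sums telescope, so gx equals a
  weighted mean of forward unit-step differences over its stencil —
  "resolution" literally counts the pixels over which the intensity change
  is averaged. The identity is tested against a brute-force oracle.
* **Disjoint, symmetric supports.** gx and gy read disjoint pixel sets for
  every R, so on integer-valued (photon-count) images the exact-tie events
  gx = ±gy are equally likely. One-sided differences share the anchor
  pixel, which correlates the components and biases the 45° tie against
  the 135° tie. Averaging over R parallel lines is also what makes the tie
  spikes genuinely shrink as R grows: a one-sided span difference
  I(j+R) − I(j) of iid noise has an R-independent distribution, so no
  span-only operator can show that suppression.

Pixels with exactly zero magnitude carry no orientation (atan2(0, 0) is
undefined) and are excluded before thresholding. The valid region excludes
the border where the stencil leaves the image (shape
(H − R − 1) × (W − R − 1)); the orientation axis convention is gy along
increasing row index, so angles are *relative to the image frame* — only
relative orientations within a frame are physically meaningful unless the
acquisition orientation is controlled.

## Parameters

* **R (averaging span, px; default 2).** R = 1 differentiates pixel to
  pixel and is maximally local but exposes integer-noise ties; R = 2–3
  suppresses them (the tie magnitudes are quantized at the count level and
  shrink relative to the magnitude scale as the stencil grows, so the
  relative threshold removes them). Larger R blurs genuinely fine texture.
* **T (magnitude threshold; default 0.05 on the normalized scale).**
  Discards weak vectors that carry noise; raising T lowers the fitted
  pedestal. The convenience rule `t_fraction = 0.10` (10% of the maximum
  magnitude) keeps noise sensitivity comparable across images.
* **B (bin width, deg; default 5).** 180/B bins. B = 1 preserves detail
  but is noisy; B = 5–10 smooths the PDF toward a cleaner Gaussian shape at
  the cost of angular resolution. B must divide 180.
* **k_max (default 3) and ε (default 0.02).** Model order is the least k
  whose R² is within ε of the maximum attained for k = 1…k_max. ε trades
  parsimony against fidelity: components explaining less than ~2% of the
  variance are not worth a family.

## Binning and normalization

Bins are half-open on the left, (0, B], (B, 2B], …, (180 − B, 180], so an
angle exactly on an upper edge belongs to that bin and 180° lands in the
last bin; folding maps 0° to 180° under the same convention. Density is
per-degree (counts / (n·B)), making the area under the histogram exactly 1
regardless of B (verified to 1e−9). Images are normalized by their maximum
by default; a percentile normalizer (clipping hot pixels) is available
behind an explicit option because photon-count outliers can compress the
intensity scale.

## Shifting

Before fitting, the tallest bin is circularly rotated to the center of the
scale (90°); ties on the maximum break to the leftmost bin for
determinism. The shift is recorded and fitted centers are mapped back to
the unshifted frame. This keeps the dominant peak away from the 0/180 seam
and measurably improves convergence. Known limitation: when two wide
families sit close to 90° apart, centering one parks the other on the
seam; since the model is not wrapped, a seam-split peak can genuinely
require an extra component, and the order-selection rule then reports
k + 1. Narrow peaks are unaffected (bins roll as whole units), and the
fitted centers themselves remain accurate.

## Fitting

Bounded trust-region least squares (`scipy.optimize.least_squares`, trf)
on (bin center, density) pairs, with bounds aₖ ≥ 0, bₖ ∈ [−90°, 270°]
(near-edge peaks on the shifted axis are representable), cₖ ∈ [B/2, 180°],
d ∈ [0, max density]. Initialization takes the k highest local maxima of a
3-bin circular moving average; up to five perturbed restarts (deterministic
jitter) guard against local minima, and each order k > 1 is additionally
warm-started from the (k − 1)-component optimum plus a small component at
the largest residual — embedding the smaller model guarantees the
attainable R² is non-decreasing in k. Reported goodness of fit is the
coefficient of determination 1 − SS_res/SS_tot, which for a least-squares
fit with the pedestal acting as intercept coincides with the squared
Pearson correlation of observed and fitted values; it is undefined
(recorded as NaN) for an exactly constant density. 95% confidence
half-widths come from the linearized covariance (Jacobian Gauss–Newton
approximation with a t quantile). A fit whose tallest component height is
below twice its 95% half-width is flagged "no dominant orientation".

A degenerate case worth knowing: a peak confined to a single bin does not
identify its center beyond that bin — the optimizer may legally place a
taller, narrower Gaussian slightly off the bin center (or off the axis
end) whose tail matches the one observed value. Real (wavy, noisy)
specimens do not produce single-bin peaks.

## Metrics

Component areas use the exact full-line Gaussian integral aₖcₖ√(2π), so
they share the scale of the unit PDF area (tail truncation at the domain
edges is the reason total Gaussian area + pedestal area only approximates
1); any fixed constant would cancel in the Gaussian-to-pedestal ratio. The
pedestal area is d·180° (the pedestal exists on the whole angular range).
Peak separations are plain |bⱼ − bᵢ| without circular wrapping, matching
the convention in which fiber-family separations are quoted. The
longitudinal panel fits k = 1 per time point and reports R², Gaussian
height a, width c, and the composite (a₁ + d)/c₁ — the total model peak
height over the width — normalized to the first (control) time point, with
an R² ≥ 0.75 flag marking very good single-Gaussian fits.

## Phantoms

`make_fiber_image` renders sinusoidal gratings: smooth, with analytically
known gradient orientation (fiber axis + 90°). Waviness is a sinusoidal
modulation of the local fiber angle with the given amplitude in degrees.
Because a sinusoidal modulation dwells at its extremes, the *noise-free*
orientation density of a wavy grating is arcsine-shaped (bimodal at ±w),
not Gaussian; with realistic photon noise it smooths into the unimodal
spread a wavy specimen shows, which is why waviness-trend tests include
Poisson noise. Multi-family phantoms support two mixing modes: `additive`
(patterns sum; where two families both have steep slope the combined
gradient points between the normals — physically, superimposed
transparencies) and `domains` (smooth random patches each showing one
family, emulating lamellar sheets occupying distinct regions; used for
crossed-fiber validation because it keeps each family's signature pure).

`make_dark_count_image` is the controlled setting for integer-noise spike
phenomenology: a smooth real-valued isotropic texture (uniform angle
continuum, zero probability of exact ties) over exact-zero plateaus
covering about half the frame, plus iid Poisson dark counts (rate 0.3 per
pixel) and a compact-support calibration bump that pins the maximum
gradient magnitude at 4.5 count units. On the plateaus all intensity
differences are small integers, so at R = 1 orientations collapse onto
exact ties at 45°, 90°, 135° and 180°(= 0°); at R = 3 the tie magnitudes
(quantized at the count level over the 3 × 3 stencil) fall below the
10%-of-maximum threshold — stable across seeds precisely because the bump
pins that maximum. The texture scale is set so its median gradient sits
well above threshold (the continuum survives) while its maximum stays
below the pin. What this phantom does *not* emulate: detector PSF, SHG
speckle statistics, or correlated readout noise; what passing shows is the
binning/threshold/folding phenomenology of quantized noise, not a claim
about any specific detector.

`sample_orientation_pdf` draws angles directly from a known model density
(components weighted by their areas, Gaussians wrapped at the seam because
folding makes the domain circular, pedestal uniform) — the ground truth
for fit-recovery tests.

## Problem sizes and study conditions

Phantom images are 256 × 256 (512 × 512 is supported; nothing in the
method depends on frame size beyond vector counts). Fit-recovery checks
use 10⁵ sampled angles at B = 5 with 20 replicate seeds; single-family
recovery uses b = 60°, c = 15° with a 20% pedestal weight, two-family
recovery b = (40°, 110°), c = (12°, 15°) — separations away from the 90°
seam case discussed above. The longitudinal series uses four time points
with waviness 8° → 18° → 30° → 45° and photon budget 60 → 25 → 12 → 6 peak
counts — a disorder ramp on both axes, as an injured-then-healing specimen
shows — analyzed at the series defaults T = 0.05, B = 5, R = 2.

## Limitations

* Non-wrapped Gaussians: peaks of wide families near the 0/180 seam are
  handled by shifting only; a wrapped (von Mises-like) variant would
  remove the k-inflation case at 90° separations but is deliberately out
  of scope.
* R²-based order selection has no penalty for complexity beyond ε; it is
  not an information criterion and can prefer an extra component when the
  density is genuinely non-Gaussian (e.g. strong undamped waviness).
* The magnitude distribution of gradients is not analyzed; only
  orientations enter the PDF.
* Metrics quantify orientation order only; they carry no biological
  interpretation by themselves.
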