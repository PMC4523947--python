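# Methods

## Model overview and assumptions

The network is a feed-forward hierarchy of 2-D competitive layers above a
Gabor-filtered retina. It deliberately omits top-down and recurrent
inter-layer connections, spiking dynamics and continuous time: the claim
under study is that *local* synaptic learning (Hebbian and temporal-trace)
plus lateral competition suffice for boundary-element selectivity and
translation invariance to emerge, so the architecture is kept to the
minimum that can express that claim.

Two lateral-interaction modes are provided per layer:

- **competitive** — the activation map is convolved with a kernel whose
  off-center coefficients are −δ·exp(−(a²+b²)/σ²) and whose center is one
  minus the off-center sum, so the kernel sums to exactly 1 and a uniform
  activation pattern passes through unchanged;
- **som** — a difference of Gaussians
  I_ab = −δ_I·exp(−(a²+b²)/σ_I²) + δ_E·exp(−(a²+b²)/σ_E²) applied at every
  offset including the center. Short-range excitation makes neighbouring
  cells co-fire, so Hebbian learning arranges similar inputs onto nearby
  cells (a topographic map).

All spatial convolutions (Gabor application and lateral filtering) use
toroidal wrap-around. This is a modelling choice: it makes shift
equivariance and the kernel-sum invariants exact, at the cost of wrapping
edge effects that are negligible while stimuli stay away from the retina
border (the stimulus generators keep them centered).

## Parameters

Full-scale preset (`paper`): 256×256 retina; four 128×128 layers;
201 afferents per layer-1 neuron (radius 6 over the retina grid) and 100
afferents for layers 2–4 (radii 6, 9, 12 over the previous layer).
Gabor bank: wavelength λ = 2 px, bandwidth b = 1.5 octaves, orientations
{0, π/4, π/2, 3π/4}, phases {0, π}, aspect γ = 0.5 — eight kernels per
location. σ is derived from λ and b with the standard half-response
bandwidth relation σ = (λ/π)·√(ln2/2)·(2^b+1)/(2^b−1). The original model
family also used longer wavelengths (4, 8, 16 px); the bank accepts extra
wavelengths (16 kernels with a second wavelength) but defaults to the
shortest-wavelength-only configuration actually exercised here.

Per-layer lateral and sigmoid constants (layers 1→4):

| quantity | 1 | 2 | 3 | 4 |
|---|---|---|---|---|
| competitive σ | 1.38 | 2.7 | 4.0 | 6.0 |
| competitive δ | 1.5 | 1.5 | 1.6 | 1.4 |
| SOM σ_E / δ_E | 1.4 / 5.35 | 1.1 / 33.15 | 0.8 / 117.57 | 1.2 / 120.12 |
| SOM σ_I / δ_I | 2.76 / 1.5 | 5.4 / 1.5 | 8.0 / 1.6 | 12.0 / 1.4 |
| sigmoid percentile | 99.2 | 98 | 88 | 91 |
| sigmoid slope β | 190 | 40 | 75 | 26 |

The sigmoid threshold α is recomputed for **every presentation** from that
presentation's lateral-filtered activation distribution (the alternative —
a running statistic — was considered and rejected for determinism and
simplicity; the choice is flagged because the convention is not forced by
the model description). With distinct activations this pins the fraction of
rates above 0.5 at (100 − percentile)%.

Learning: rate k = 0.1 (constant), trace decay η = 0.8, layers trained
sequentially bottom-up with lower layers frozen, 50 epochs per layer by
default. k and the epoch counts are free parameters of the model (no
published value); 50 epochs is comfortably past the point where the
per-epoch weight-change norm plateaus for the Hebb studies. The
translation-invariance study defaults to 100 epochs: with a 2×2 location
grid each object pass contributes only (locations − 1) trace-driven
updates, and at 50 epochs location binding is still incomplete at desk
scale. The per-neuron trace is reset to zero at object boundaries so
temporal binding never spans two different objects.

Desk-scale preset (`test_small`): 64×64 retina, 32×32 layers, 50
connections per neuron, connection radii (3, 3, 4.5, 6). The radii are the
full-scale values halved, not quartered like the grid, so that every neuron
still has more distinct in-reach sources than connections. The lateral and
sigmoid constants are kept verbatim — they were originally tuned for
32×32 layers in this model family, which is exactly the small preset's
layer size.

## Connectivity calibration

Afferents are sampled from an isotropic 2-D Gaussian over the pre-layer
grid around each neuron's topologically corresponding position, rounded to
the grid, paired with a uniformly drawn channel (Gabor kernel index for
layer 1), and redrawn on duplicates until the neuron holds its exact
connection count. The Gaussian scale is calibrated so that ≈67 % of the
*realized connections* fall within the configured radius. Calibrating the
continuous distribution instead would miss by ~1.5 percentage points,
because grid rounding and duplicate rejection flatten the high-probability
center cells; the calibration therefore solves for the effective raw-draw
count M with Σ_c (1−(1−p_c)^M) = n_conn and bisects the scale on the
resulting expected in-radius fraction. Where the 67 % target is
unattainable (neighbourhoods with fewer distinct in-radius sources than
connections, as in the small preset's upper layers), the continuous-mass
calibration is used as a best effort.

## Stimuli

Study-1 shapes: n vertices on a circle (circumradius = retina/4 by
default), each side a circular arc with signed sagitta s·(chord length);
s = ±0.25 for concave/convex, 0 for straight, ±0.45 for the sharp variants
(p = 4). The five-way element set for the V4-style closed shapes maps
{sharp convex, medium convex, broad convex, medium concave, broad concave}
to s = {+0.45, +0.30, +0.15, −0.30, −0.15}; vertex angular separations are
configurable (the 135°/135°/90° set is the default) and must sum to 360°.
Shapes are rendered as white outlines on black (stroke ≈ 2 px via a disc
dilation; a filled-silhouette mode is available behind a flag — the outline
default matches the filter convention of a bright bar on dark ground).
Rounding to the pixel grid is symmetric (half away from zero), which makes
mirror rendering an exact column flip and integer translations exact pixel
shifts; both are tested properties, and the renderer refuses shapes that
leave the retina rather than clipping them.

The "natural-like" generator produces smooth filled blobs whose radius
function is a truncated Fourier series with harmonic amplitudes ∝ 1/k
(default 4 harmonics, scale 0.12): closed, curvature-continuous
silhouettes that are deterministic under seed. It emulates the *statistical
decoupling* of boundary elements across a varied object population — the
property the theory needs — but none of the photographic structure of real
object images (no texture, shading, depth or internal contours). Tests
passing on blobs therefore support the learning mechanism, not claims
about performance on photographs.

Presentation sequences follow the saccade assumption: within one object,
all grid locations are visited (fixed raster order) before the orientation
advances, and all of an object's transforms appear before the next object;
boundary flags mark the transitions for the trace reset.

## Analyses

**Selectivity.** A cell counts as selective for an element iff its rate is
within 5·10⁻⁵ of 1 for *every* presentation of an object containing the
element and within 5·10⁻⁵ of 0 for every other presentation, across all
tested locations and orientations. The window is deliberately strict; it
is the headline count and is checked against a brute-force oracle.

**Single-cell information.** I(s, R) = Σ_r P(r|s) log2[P(r|s)/P(r)] with
rates quantized into 10 equal-width bins over [0, 1] (bin count
configurable; the measure is reported per cell as the maximum over element
categories). In the n-sides × p-conformations design the ceiling is
log2(p) bits. Implementation is vectorized and verified to 10⁻¹² against
an independent probability-table oracle.

**Boundary segmentation.** Contours are resampled at uniform arc length
(720 samples), coordinates smoothed with a periodic Gaussian (σ = 4
samples), curvature computed from central differences, and cut points
placed where |dκ/ds| exceeds a threshold. The default threshold is
relative — 5 % of the contour's maximum |dκ/ds|, with an absolute floor
below which the contour counts as constant-curvature (a circle yields one
segment) — because corners sit orders of magnitude above arc-interior
values. The two derivative lobes flanking a corner are merged by circular
binary closing, and the smoothed transition zones are trimmed from segment
curvature means. `calibrate_segmentation_threshold` recovers an absolute
threshold from a calibration polygon (exactly n segments) when a fixed
threshold is preferred.

**Tuning heatmaps.** Mean rate per (curvature, angular position) bin —
16 angular × 8 curvature bins by default — over all presentations whose
segments fall in the bin; unobserved bins are NaN-flagged, never
zero-filled. Peak counting uses the 8-neighbourhood with the angle axis
circular, strict dominance over neighbours (a plateau counts once, and
only with at least one strictly lower neighbour, so a flat map has no
peaks), and a floor of 60 % of the heatmap mean. The idealized-V4
comparison correlates the map with a 2-D Gaussian tuning surface (angle
wrapped) over observed bins.

## Numerical choices

- FFT-based circular convolution throughout; lateral kernels are built on
  the full torus with minimal-image distances, so the competitive kernel's
  sum-to-one holds to machine precision.
- Sigmoid exponent clipped at ±700 to avoid overflow at the steep slopes.
- Weight renormalization raises an error on an all-zero weight vector
  rather than silently dividing by zero.
- All randomness flows through seeded `numpy` generators; a (config, seed)
  pair reproduces every output bit-for-bit on one platform.

## Known limitations

- Desk-scale results are directional, not numerical: counts of selective
  cells at 32×32-layer scale are not comparable to full-scale counts.
  In particular, the self-organizing map's advantage over the plain
  competitive network in selective-cell counts reproduces decisively in
  the low-density regime (p = 2, where the SOM yields several times more
  selective cells) but is seed-level noise at p = 4 at this scale; the
  high-density advantage appears to require the full-scale ratio of cells
  to objects. The SOM's map formation itself (spatial clustering of
  maximal-information cells) is verified directly.
- The χ² comparison of peak-count distributions is not implemented as a
  headline statistic; peak counting itself is oracle-tested, and users can
  apply any contingency test to the returned counts.
- Sequences are rendered eagerly; full-scale rotation × location sweeps
  are memory-hungry and intended for batch runs, not the test suite.
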