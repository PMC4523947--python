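# boundarynet

A hierarchical competitive-network model of how neurons in the intermediate
primate ventral visual stream (V4 / TEO) come to encode **localized boundary
contour elements** — a concave, straight or convex stretch of an object's
outline at a particular angular position in the object's frame of reference —
through unsupervised, biologically local learning.

The package is for computational neuroscientists who want to simulate and
analyse this class of model at desk scale: it bundles the stimulus
generators, the network, the learning rules and the full analysis battery
(strict element-selectivity counting, single-cell information,
receptive-field backtracing, curvature × angular-position tuning).

## The model

Images on a simulated retina are pre-processed by an even Gabor filter bank
(V1 simple-cell-like; four orientations × two phases, wavelength 2 px),

    g(x, y) = exp(−(x′² + γ² y′²) / 2σ²) · cos(2π x′/λ + ψ),

and fed to a stack of 2-D neuronal layers. Each neuron draws a fixed number
of afferents from a Gaussian neighbourhood of the layer below (calibrated so
the configured radius contains ≈67 % of its connections). A forward pass per
layer is

1. linear activation  h_i = Σ_j w_ij y_j
2. lateral interaction — either *competitive* (a sum-to-one kernel with an
   inhibitory Gaussian surround) or a *self-organizing map* (Mexican-hat
   difference of Gaussians, short-range excitation + long-range inhibition)
3. contrast enhancement  y = 1 / (1 + exp(−2β(r − α))), with the threshold α
   set to a fixed percentile of the layer's activations so firing stays
   sparse (e.g. the 96th percentile ⇒ 4 % of rates above 0.5).

Feed-forward weights learn with the Hebb rule δw_ij = k·y_i·y_j, or with the
**temporal trace rule**

    δw_ij = k · r̄_i^(τ−1) · y_j,   r̄_i^τ = (1−η) y_i^τ + η r̄_i^(τ−1),

which binds inputs that occur close together in time — the mechanism for
translation invariance when each object is swept across retinal locations
before the next object appears. Weight vectors are renormalized to unit
length after every update.

Training on all p^n closed shapes built from n sides × p boundary
conformations statistically decouples the n·p elements, so output neurons
specialize for single elements (e.g. "concave on top") rather than whole
shapes; a winner-per-pattern network with N outputs can only keep pairwise
object representations distinct while n(n−1)/2 ≤ N, which forces the switch
to element coding as the object population grows.

## Worked example

```python
from boundarynet import run_study, STUDY_PRESETS

res = run_study(STUDY_PRESETS["study1"])   # n=3 sides, p=2 conformations,
                                           # Hebb + competitive, desk scale
print("selective cells (untrained):", res.n_selective_untrained)
print("selective cells (trained):  ", res.n_selective_trained)
print("max single-cell information:", res.info_trained.max_info.max())
```

prints

```
selective cells (untrained): 9
selective cells (trained):   38
max single-cell information: 1.0
```

Training the 3-layer network on the 8 closed shapes (2³ combinations of
concave/convex on three sides) raises the number of third-layer cells that
fire ≈1 for *every* object containing one particular boundary element and
≈0 for every object lacking it (window 0.99995 ≤ y ≤ 1 vs y < 0.00005) from
9 to 38; the best cells reach the design's information ceiling of
log2(p) = 1 bit about "which conformation is on this side".

The same machinery runs the other study designs: `study1_trace` (objects
swept over a 2×2 location grid, trace learning → translation-invariant
element selectivity), `study1_som` (map-forming lateral interactions),
`study2`/`study2_trace` (closed shapes from five convex/concave element
types at fixed vertex separations, rotated through 360°, analysed with
curvature × angular-position heatmaps), and `study3_like` (smooth random
blob silhouettes). Full-scale presets (256×256 retina, 128×128 layers)
exist but are long-running; the `*_paper` entries in `STUDY_PRESETS` hold
their configurations.

A thin CLI wraps the library:

```
boundarynet train --preset study1 --seed 0 --out run/
boundarynet test  --preset study1 --network run/network.npz --out run/
boundarynet analyze run/responses.csv --preset study1 --out run/
```

## Layout

- `src/boundarynet/stimuli.py` — shape families, rendering, blobs, sequences
- `src/boundarynet/gabor.py` — the retinal filter bank
- `src/boundarynet/netcore.py` — connectivity, lateral filters, learning
- `src/boundarynet/experiments.py` — study drivers, capacity threshold,
  mirror-image probe
- `src/boundarynet/analysis.py` — information, selectivity, backtracing,
  boundary segmentation, tuning heatmaps
- `src/boundarynet/config.py`, `cli.py` — configuration, persistence, CLI
- `docs/methods.md` — modelling choices, parameters, limitations
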