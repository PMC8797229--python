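# Methods

`microtrack` analyses time-lapse movies of rod-shaped bacteria growing on
2-D surfaces (agarose pads, microfluidic growth chambers). The pipeline is
segmentation → frame-to-frame tracking → lineage reconstruction → feature
extraction, with two trainable U-Nets at its core and a synthetic
microcolony simulator that supplies complete ground truth so every stage
can be trained and tested at desk scale.

## Segmentation model

A U-Net encoder–decoder maps one normalised phase-contrast plane to a
cell-probability plane. Depth (number of 2× down-samplings, default 4) and
base filter count (default 64, doubling per level) are configurable;
reduced variants trade accuracy for speed. Up-sampling is 2×
nearest-neighbour followed by a 3×3 convolution, which avoids the
checkerboard artifacts of transposed convolutions; skip connections are
channel concatenations; the head is a 1×1 convolution with a sigmoid.
Batch normalisation is off, following the original U-Net lineage.

The network core is a compact CPU implementation in numpy: im2col + BLAS
matmul convolutions with analytic gradients, verified against central
finite differences to ~1e-9 relative error in the test-suite. The
*desk-scale profile* used throughout the tests and the acceptance script is
depth 3 with 16 base filters trained on 64×64 crops; one optimisation step
takes ~85 ms on a single core, so the models used in the end-to-end checks
train in a few minutes.

Inference: frames are percentile-normalised (0.1/99.9, order-statistic
percentiles, which makes normalisation exactly idempotent), frames larger
than 512×512 are cropped into overlapping windows (overlap 128 px) and the
window outputs blended back with weights that taper linearly to zero at
interior window edges. The blend is computed as *reference + weighted
deviation from reference*, so it is bit-exact when all windows agree. The
probability plane is thresholded at 0.5 and labelled by plain 8-connected
components with a 20 px minimum area; there is no watershed or other
morphological post-processing — separating touching cells is the trained
model's job, steered by the weight maps below.

## Weighted loss and weight maps

Both models train with a pixelwise-weighted binary cross-entropy:

    L = Σ_p w_p · BCE(gt_p, pred_p) / Σ_p w_p

normalised per sample by its weight-map sum so every sample updates the
model by a comparable amount. Predictions are clipped to [1e-7, 1 - 1e-7].

Segmentation weight maps emphasise what matters for separating touching
rods. With a labelled ground-truth frame:

- each cell's morphological skeleton gets `w_skeleton` (default 4);
- cell bodies ramp from 1 at the boundary up to (but strictly below)
  `w_skeleton` by normalised distance-to-boundary;
- the *border region* — background pixels within `d_border` (2 px) of two
  or more distinct cells — ramps up to `w_border_skeleton` (default 8) on
  its skeleton, the highest weight anywhere;
- the one-pixel cell/border contact ring gets `w_interface` (default
  0.25): those interfaces are arbitrary at pixel resolution and the model
  should not be forced to learn them;
- plain background gets `w_background_base` (default 0.1).

The numeric defaults are this package's own choices — what is fixed is the
ordering (border skeleton > cell skeleton > body ramp > interface), which
the tests assert pixelwise. The binary target is each cell's footprint
eroded by one pixel where two labels touch, so targets never fuse
neighbours and the inter-cell valley is learnable.

*Variable background weighting*: during training the background part of
each weight map is replaced by the model's own prediction (plus the base
floor). A confident false positive on background debris then carries
weight ≈ 1 and is punished hard, while correctly ignored background stays
cheap — the model learns to discard debris quickly without inflating the
loss elsewhere.

Tracking weight maps put the maximum weight on the target cell's skeleton
and weight every other cell's pixels by `exp(-d/δ)` of their Euclidean
distance `d` from the target (δ = 32 px): nearby distractors, the ones the
model could plausibly confuse, matter most. The functional form and δ are
package choices; only the ordering (nearer distractor > farther) is
asserted.

## Tracking and lineage

For each cell in the previous frame a 256×256 window (configurable; 64×64
in the desk-scale profile) is cropped around the cell's previous centroid
and clamped inside the frame by shifting, never shrinking. Four planes are
stacked: previous phase, binary mask of the query cell, current phase,
binary mask of all current cells. The tracking U-Net (4 input planes)
outputs one probability plane covering the tracked cell — or both
daughters after a division.

Assignment is deliberately simple: each current-frame cell is scored by
the mean predicted probability over its pixels inside the crop; candidates
score ≥ θ (default 0.5); queries take at most their top two candidates
(two → division, one → continuation, none → exited), conflicts are
resolved greedily by descending score with losers falling back to their
next candidate, and current cells claimed by nobody become orphans (cells
that entered the field). With the ground-truth oracle in place of the
network this decision rule reproduces simulator assignments with zero
errors, including under 10 px/frame drift — the crop recentring absorbs
translations.

Pole ages follow the old/new-pole convention. After a division the septum
is the midpoint of the daughters' mutually nearest endpoints (endpoints =
extremal points of the skeleton path); each daughter's endpoint nearest
the septum is its new pole, and the daughter whose far endpoint matches
the mother's old pole appends 'O' to its pole history while its sibling
appends 'N'. Founders have age-unknown poles: their first division
initialises pole coordinates but appends no letter, because the letter
records which of the *mother's* poles a daughter inherited, which is
undefined for an age-unknown mother. The simulator uses the same
convention, so reconstructed histories can be compared letter-for-letter
to ground truth. Degenerate daughter geometry (a mask too round to orient)
leaves poles unknown and withholds the letters.

## Features and statistics

Cell length is the geodesic length of the skeleton path between the two
endpoints plus the distance-transform half-width at each end, in μm. Other
tools use bounding-ellipse axes; the definitions differ by a roughly
constant offset for rods, which matters when comparing absolute lengths
across tools. Fluorescence is the raw mean channel intensity over the
cell's pixels (no background subtraction by default).

The growth rate over one generation is the average of the per-step
relative increments (L_t − L_{t−1}) / L_{t−1} / Δt in 1/hr, computed from
birth to the frame before the cell's own division. This discrete estimator
converges to (e^{rΔt} − 1)/Δt for exponential growth at rate r — the
discretisation bias is part of the definition and deliberately not
corrected, so results are comparable with the standard practice. Cells
observed fewer than 3 frames are excluded; a configurable first-frame
cutoff can additionally exclude cells that enter the field late.

Pole-age statistics group generation growth rates by history string:
single-letter groups (O vs N) are compared with a two-sided unpaired
t-test, longer generations with a one-way ANOVA plus Tukey HSD post-hoc
(scipy / statsmodels). Groups with n < 2 are dropped with a warning. No
additional multiple-testing correction is applied beyond Tukey.

## Synthetic microcolonies

Agents are 2-D spherocylinders with exponential elongation
(length × e^{r·dt}), stochastic division thresholds, and pairwise-repulsion
mechanics: overlapping capsules are translated apart along the vector
joining their closest axis points until the worst overlap is below 0.05 μm
(a fixed-point iteration, not rigid-body physics — sufficient to create
the crowding and neighbour-contact regimes the models must handle).
Divisions split at mid-length plus Gaussian asymmetry noise; the daughters'
lengths sum to the mother's length minus one cap width (the septum
consumes one cap), and pole bookkeeping follows the convention above.

Default conditions emulate *E. coli* microcolonies on minimal-medium pads
imaged every 5 min at 100× (0.129 μm/px): mean elongation rate 0.6 1/hr
with 10% CV (per-cell lognormal), division around 4.5 μm with 10% CV
(lognormal threshold sampled at birth, which desynchronises divisions),
cell width 1 μm, near-symmetric division (asymmetry SD 2%).

Rendering: bright background (0.7) − dome-shaped interior darkening
(0.45) + Gaussian halo outside the cell boundary (amplitude 0.25,
σ 0.25 μm), Gaussian blur (σ 1 px), additive sensor noise (σ 0.02),
clipped to [0, 1]. Optional per-strain fluorescence channels and global
per-frame drift (integer or subpixel) are supported. What the renderer
does *not* emulate: real phase-contrast optics (no point-spread function),
focus drift, uneven illumination, debris, or segmentation-resistant
morphologies (filamentation under stress). Tests passing on synthetic
movies therefore demonstrate that the pipeline machinery is correct and
trainable — not that a desk-scale model transfers to real microscopes,
which needs training on real annotated data at full scale.

An `old_pole_penalty` parameter (default 0) multiplies the elongation rate
of daughters whose latest inherited pole is old by (1 − penalty). It
exists so parameter-recovery tests can target a known effect size: with
penalty 0 the pole-age analysis must stay null-calibrated, with penalty
0.10 and ~2000 cells it must detect O < N essentially always. A
`mechanics=False` fast path skips spatial relaxation and rendering for
these statistics-scale colonies; growth/division/pole bookkeeping is the
identical code.

## Numerical and design choices

- Coordinates are 0-based row-major (row, col), origin top-left; crop
  windows are half-open. Physical units: μm, minutes (interval), 1/hr
  (rates).
- Seeding: one global seed fans out to per-stage seeds via
  `SeedSequence`; identical seed + config gives bit-identical movies,
  weight maps, training histories and feature tables on the same platform.
- Training checkpoints are written only when an epoch's mean loss reaches
  a new minimum; a non-finite loss aborts with a diagnostic rather than
  continuing silently.
- Degenerate inputs: constant images normalise to zeros; empty frames give
  uniform background weight maps; masks under 2 px raise on length
  extraction; a degenerate skeleton falls back to the equivalent-circle
  diameter (flagged by its value, not silently plausible).
- The object-level error counting treats a prediction as correct when >3/4
  of its pixels lie in a single unclaimed ground-truth cell; a prediction
  covering ≥25% of each of two ground-truth cells is a merge (2 errors); a
  split costs 1 error; the 25% threshold is a package choice
  (configurable). Claims are one-to-one so a satisfied ground-truth cell
  cannot validate a second prediction. Division timing is compared with a
  ±3 frame tolerance, because the exact division frame is genuinely
  ambiguous even for humans.

## Known limitations

- The numpy network core is single-image-batch oriented and CPU-bound;
  full-scale profiles (depth 4, 64 filters, 512² inputs) train only with
  patience. The architecture and training contracts are the point here,
  not throughput.
- No gap-closing: a cell that leaves and re-enters the field becomes a new
  cell. No temporal smoothing of segmentation across frames.
- nd2/czi readers are out of scope (TIFF/OME-TIFF only); the reader
  interface is the extension point.
- The mother-machine (1-D chamber) geometry is not supported; the package
  targets 2-D surfaces.
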