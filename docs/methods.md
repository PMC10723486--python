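# Methods

This note documents the model, the defaults and the numerical choices
behind the package, and what the synthetic evaluation does and does not
demonstrate.

## The model and its assumptions

The method rests on two assumptions about H&E-imaged layered tissue:

1. tiles that are lattice-adjacent are, with high probability, from the
   same or transitioning histology, while two tiles drawn at random from
   a dataset usually are not — so adjacency is a free supervisory signal
   for metric learning; and
2. a minimum-cost path through a graph whose edge weights are embedding
   distances between adjacent tiles will spend its length inside
   visually homogeneous layers and cross boundaries only where it must,
   so position along the path is a meaningful depth coordinate.

Neither assumption requires expression data, which is what lets the
resulting depth axis be used to *analyze* expression without
circularity.

## Count and tile normalization

Counts are normalized per slide: `X̃[s,g] = ln(1 + t·X[s,g]/(ΣX/|S|))`
with `ΣX/|S|` the average **total** count per spot and target
`t = 10⁴`. The average is over total spot counts (not per gene), which
makes the transform invariant to a global scaling of the raw counts.
Natural log is used, matching standard single-cell practice. Genes are
not filtered and no batch correction is applied — trajectories are
meant to be read on this common normalized scale.

Tile pixels are standardized per channel with mean and standard
deviation pooled over **all tiles of the dataset** (all slides that
train one encoder); per-slide statistics are available by passing a
single-stack statistic. The statistics are stored on the normalized
stack and in a JSON sidecar, and the encoder records them: embedding
tiles normalized with different statistics is a contract error, since
the embedding space is only defined relative to the training transform.

## The encoder

The embedding function is a pure-numpy model in two parts:

- a **frozen convolutional feature bank**: tiles are resized to 32×32,
  passed through 8 seeded random 5×5×3 filters (zero-mean, unit-norm),
  rectified and 4×4 average-pooled, and concatenated with per-tile
  channel means and standard deviations (398 features). Random
  convolution features preserve exactly the cues that distinguish
  layers here — color and texture orientation — without needing to be
  learned;
- a **trainable MLP projection head** whose output is `f`. Gradients of
  the triplet loss are computed analytically and optimized with
  minibatch SGD (momentum 0.9, weight decay 1e-4). The training
  distance is mean squared error; graph weights and alignment use
  Euclidean distance on the same vectors.

`encoder_size="small"` (default) uses a 398→64→32 head and trains in
seconds on one CPU. `encoder_size="full"` switches to a 3-layer head
with hidden dimension 2048 and the full-scale recipe (margin 0.001,
1000 epochs, batch 768, learning rate 0.05) for users who want the
published hyperparameters on larger data. Deliberate choices:

- **the loss acts on the projection-head output and the same vectors
  are used downstream** — exposing intermediate features instead is
  possible but would decouple the traversal metric from the trained
  objective;
- **negatives exclude the anchor's neighbors**, not just the anchor, so
  a sampled "negative" can never be a legal positive;
- **no augmentations**: flips/rotations destroy the cell-orientation
  cue that distinguishes otherwise similar layers (e.g. inner vs outer
  smooth muscle), so they are intentionally absent;
- **determinism**: every stochastic step (initialization, per-epoch
  triplet pools, pair sampling) is driven by integer seeds; identical
  config + seed reproduces embeddings bit-exactly.

## Traversal

Edge weights of exactly zero are legal (identical embeddings); no
epsilon floor is added. Dijkstra runs on the compound key
(cost, hop count), and the path is reconstructed from the start anchor
choosing at each step the smallest-id neighbor still on an optimal
path. Ties are therefore broken by fewest spots, then lexicographically
smallest spot-id sequence — traversals are reproducible across
platforms. Anchors may be any in-tissue spots; placing them on the
outer tissue edges, roughly perpendicular to the layering, is a usage
guideline, not a precondition. Anchors in different connected
components raise a no-path error naming the component sizes.

## Alignment and trajectories

Assignment ties (equidistant path tiles) go to the smallest path index:
stable, and orientation-respecting. Averaging uses normalized
expression, so set-size-weighted trajectory rows reconstruct the global
per-gene mean exactly (tested to 1e-10). Length normalization maps path
index `i` to position `i/(k−1)` — uniform spacing, treating `k` as the
trajectory's sampling rate; spacing proportional to cumulative edge
weight is available as `length_normalize_weighted`. Interpolation is
piecewise linear at positions 0.00…1.00; endpoints are copied exactly.

External depth-based aligners are adapted by rounding each spot's
scalar depth half-away-from-zero and re-indexing the unique levels to
consecutive integers; averaging by level assumes levels are linearly
spaced along the depth axis (adequate when no levels are missing
between the extremes).

## Anchor-pair sampling and comparison

"Reasonable" start/end pairs are built from user-supplied edge spot
lists sorted by the y pixel coordinate; start `aᵢ` is paired with ends
in a window of radius r = 15 around its position-matched end. When
|A| ≠ |B| the window is centered at `round(i·(|B|−1)/(|A|−1))`.
Automatic tissue-edge detection is out of scope — edges depend on the
orientation and architecture of the specific sample — but
`edge_spots` covers the common band-layered rectangular case. Pairs
are sampled uniformly without replacement. The average-trajectory band
is the normal approximation `mean ± 1.96·sd/√n`; with n = 1 the band
is omitted rather than reported as zero. Spearman's ρ uses average
ranks for ties and is refused (not returned as NaN) for constant
inputs.

## Segmentation

Boundary annotations are ordered one-spot-thick sets of lower-layer
spots facing the next layer. Walking the path, the **first** index
crossing boundary `B_l` closes layer `l−1`: layer `l` covers path
indices `c_l < p ≤ c_{l+1}`, so the crossing tile stays with the layer
it is leaving — consistent with the boundary spots being lower-layer
tissue; later re-entries into an already-crossed boundary are ignored.
Crossings out of annotation order are an error (the annotation
direction does not match the traversal). A path-tile assignment set
that spans both sides of a boundary follows its path tile's run — a
known, documented coarseness of path-based quantization. ARI is the
standard permutation-model index; labels are compared on the
intersection order of spot ids.

## The synthetic slide generator

The generator emulates what the method needs from real data and
nothing more: a Visium-convention hex grid; contiguous equal-width
bands of spots as layers; per-layer tile appearance = base RGB color +
oriented sine stripes (amplitude 40, period 6 px) + Gaussian pixel
noise; counts drawn per spot and gene from Poisson with layer-specific
means — the minimal count law, sufficient to exercise normalization
and averaging. `default_layers` gives each layer a distinct color, a
distinct stripe orientation, and one marker-gene block peaking at mean
60 in its home layer and decaying geometrically (×0.3 per layer of
distance) to a baseline of 5 — expression transitions across layers
are graded, not step-like, so each marker's expected trajectory is
strictly monotone in distance from its home layer. Evaluation runs use
a 20×20 grid (400 spots), 20 genes, 3 layers, tile side 16 px, and the
small encoder for 20 epochs — sizes at which the full method runs in
seconds while leaving each stage statistically distinguishable from
noise.

What passing on this generator does **not** show: robustness to real
H&E stain variability, nuclei-scale morphology, irregular or curved
layer boundaries, tissue folds/tears, or multi-fragment slides. The
generator's layers are straight bands by design (a curved-band option
is a non-goal); disjoint band groups can emulate multiple fragments as
a stretch test only.

## Known limitations

- Visually similar but distinct layers (e.g. faded staining) can be
  aligned together; this is inherent to an image-only metric.
- Segmentation granularity is bounded by assignment-set size: one
  mislabeled path tile drags its whole set.
- The small encoder's frozen feature bank is tuned to color/orientation
  texture; tissue whose layers differ only in higher-order morphology
  would need the large head and realistic training scale.
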