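# atat — automated tissue alignment and traversal for spatial transcriptomics

Spatial transcriptomics (e.g. 10x Visium) overlays a spot × gene count
matrix on an H&E image of the same tissue section. Comparing gene
expression *across* sections is hard because every section has its own
shape, orientation and depth; pathologists solve it by manually
annotating histological layers, which does not scale. This package
automates that step using only the image: it learns a spatially aware
embedding of the H&E tile centered on each spot, traverses the tissue
along a histologically coherent path between two user-chosen anchors,
and projects the whole slide onto that path — turning the 2-D slide
into 1-D gene expression trajectories that can be averaged and compared
across samples. It is aimed at anyone analyzing layered tissue
(gut wall, cortex, skin, ...) who wants expression-by-depth profiles
without manual segmentation, and without the circularity of defining
layers from the expression data being analyzed.

## Method

1. **Tile embedding (self-supervised).** One square tile per spot, side
   equal to the spot diameter, standardized per channel over the
   dataset. An encoder `f` is trained with triplet loss
   `L = max(0, m(f(a), f(p)) − m(f(a), f(n)) + α)` where the positive
   `p` is a lattice neighbor of the anchor `a`, the negative `n` a
   random non-neighbor, `m` is mean squared error, and the margin
   α = 0.001. Adjacent (hence histologically similar) tiles are pulled
   together; unrelated tiles are pushed apart — no labels needed.
2. **Traversal.** The hexagonal spot lattice becomes a graph `(V, E)`
   with edge weights `W[i,j] = ‖f(sᵢ) − f(sⱼ)‖₂`. The traversal
   `P* = argmin_P Σ W[i,i+1]` between the two anchors is found with
   Dijkstra's algorithm; it respects spot adjacency, so no spot is
   skipped.
3. **Alignment.** Every spot is assigned to its nearest path tile,
   `C(s) = argmin_{p∈P*} ‖f(s) − f(p)‖₂`; the assignment sets
   `S_p = {s | C(s) = p}` partition the slide. Averaging the normalized
   expression `X̃[s,g] = ln(1 + t·X[s,g]/(ΣX/|S|))` (target count
   t = 10⁴) within each `S_p` gives the trajectory matrix `X̂` (k × |G|).
4. **Comparison.** Each trajectory is length-normalized onto 101
   relative positions in [0, 1] (`X̄`, 101 × |G|) by linear
   interpolation, then averaged with 95% confidence bands, compared by
   Spearman's ρ, or quantized into discrete layers at annotated
   boundary crossings and scored against other segmentations with the
   Adjusted Rand Index.

Because no public layered-tissue bundle ships with the package, the
`fixtures` module simulates one — hex grid, striped/colored band image,
Poisson counts with layer-specific means and graded marker genes — with
known ground truth, so the whole method is testable end to end.

## Worked example

```python
import atat
from atat.fixtures import default_layers

grid  = atat.make_visium_grid(20, 20, spot_diameter_px=16)
slide = atat.make_layered_slide(grid, default_layers(3, 20), layer_axis="x", seed=7)

tiles   = atat.extract_tiles(slide.image, grid)
tiles_n = atat.normalize_tiles(tiles, atat.compute_tile_stats([tiles]))
encoder = atat.train_encoder(tiles_n, grid, atat.TrainConfig(epochs=20, seed=1))
emb     = atat.embed_tiles(encoder, tiles_n)

graph = atat.build_graph(grid, emb)
path  = atat.shortest_path(graph, atat.edge_spots(grid, "left")[10],
                                  atat.edge_spots(grid, "right")[10])
assign = atat.assign_spots(emb, path)
counts = atat.normalize_counts(
    atat.CountMatrix(slide.counts, list(grid.spot_ids), slide.gene_ids))
traj   = atat.average_along_path(counts, assign)
```

Running `python examples/03_traverse_and_align.py` (which is exactly
this) prints:

```
path: 21 spots, total cost 27.926
spots aligned to a path tile of their own layer: 99.0%
trajectory of layer-0 marker gene-0000 along the path:
[6.87 6.83 6.86 6.79 6.8  6.85 6.86 5.78 5.49 5.72 5.87 5.81 5.78 5.69
 4.94 4.94 4.96 5.06 4.93 5.06 4.99]
```

The 21-spot path crosses the three synthetic layers left to right; 99%
of spots are assigned to a path tile inside their own layer, and the
layer-0 marker's trajectory steps down as the path leaves its home
layer — the expression-by-depth profile the method exists to produce.
The other scripts in `examples/` cover simulation, encoder training,
anchor-invariance comparison, segmentation scoring, and the one-call
pipeline; the same stages are available from a shell via the `atat`
command (`atat simulate|train|traverse|align|trajectory|compare|
sample-paths|segment|ari|run`).

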