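"""Simulate a layered Visium-style slide and write it as a standard bundle.

Builds a 20x20 hexagonal spot grid, renders three vertical tissue bands
(distinct base color, stripe orientation and Poisson gene expression per
band) and writes the image/positions/counts bundle any spatial pipeline
can read.
"""
from pathlib import Path

import numpy as np

import atat
from atat.fixtures import default_layers

grid = atat.make_visium_grid(n_rows=20, n_cols=20, spot_diameter_px=16)
slide = atat.make_layered_slide(grid, default_layers(3, 20), layer_axis="x", seed=7)

outdir = Path("scratch/example_bundle")
paths = atat.write_slide_bundle(slide, outdir)

print(f"spots: {grid.n_spots}  image: {slide.image.shape}  genes: {len(slide.gene_ids)}")
print(f"spots per layer: {np.bincount(slide.truth_labels)}")
print(f"bundle written to {outdir}: {sorted(p.name for p in paths.values())}")
# The three layer counts are roughly equal because the bands split the
# slide into equal-width thirds; the bundle is the input for the other
# examples.
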