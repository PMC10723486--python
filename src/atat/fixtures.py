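"""Synthetic Visium-style slides with known ground truth.

Real tissue bundles (slide image + positions + counts) are large and not
always shareable, so this module fabricates them: a hexagonal spot grid,
a stained-looking image in which contiguous bands of spots act as
histological layers, and Poisson counts whose per-gene means are
layer-specific.  Each layer's tiles get a distinct base color and an
oriented stripe texture — in real tissue, cell orientation is often what
distinguishes otherwise similar layers (e.g. inner vs. outer smooth
muscle), so orientation is the texture cue the generator encodes.

Everything is deterministic given the single integer seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError
from .grids import SpotGrid

#: Peak-to-mean amplitude of the stripe texture, in 8-bit intensity units.
STRIPE_AMPLITUDE = 40.0
#: Stripe wavelength in pixels.
STRIPE_PERIOD_PX = 6.0


@dataclass
class LayerSpec:
    """Rendering and expression recipe for one synthetic tissue layer.

    ``gene_means`` are the expected Poisson counts per spot for every
    gene; its length fixes (and must match) the global gene count.
    """

    layer_id: int
    color_mean: tuple[float, float, float]
    texture_angle: float  # degrees; orientation of the stripe texture
    noise_sd: float
    gene_means: np.ndarray

    def __post_init__(self) -> None:
        self.gene_means = np.asarray(self.gene_means, dtype=float)
        if self.layer_id < 0:
            raise InvalidArgumentError("layer_id must be >= 0")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")
        if np.any(self.gene_means < 0):
            raise InvalidArgumentError("gene_means must be nonnegative")


@dataclass
class SyntheticSlide:
    """A rendered slide with its ground truth.

    ``counts`` rows follow ``grid`` spot order (in-tissue spots);
    ``truth_labels`` give each spot's generating layer id.
    """

    grid: SpotGrid
    image: np.ndarray  # (H, W, 3) uint8
    counts: np.ndarray  # (n_spots, n_genes) int
    truth_labels: np.ndarray  # (n_spots,) int
    gene_ids: list[str] = field(default_factory=list)

    @property
    def n_layers(self) -> int:
        return len(np.unique(self.truth_labels))


def make_visium_grid(n_rows: int, n_cols: int, spot_diameter_px: int) -> SpotGrid:
    """Build a full rectangular Visium-style hex grid.

    Array row ``r`` holds ``n_cols`` columns of parity ``r mod 2``
    (columns ``r%2, r%2+2, ...``), the Visium convention in which
    same-row neighbors differ by 2 in ``array_col``.  Pixel centers are
    spaced one spot diameter per array-column unit horizontally and
    ``round(diameter * sqrt(3))`` per row vertically, so square tiles
    with side equal to the spot diameter never overlap.  All spots are
    flagged in-tissue.
    """
    if n_rows < 1 or n_cols < 1 or spot_diameter_px < 1:
        raise InvalidArgumentError(
            "n_rows, n_cols and spot_diameter_px must all be >= 1"
        )
    d = float(spot_diameter_px)
    margin = d
    row_pitch = round(d * math.sqrt(3.0))
    ids, arr, pix = [], [], []
    for r in range(n_rows):
        for j in range(n_cols):
            c = 2 * j + (r % 2)
            ids.append(f"spot-{r:03d}-{c:03d}")
            arr.append((r, c))
            pix.append((margin + r * row_pitch, margin + c * d))
    return SpotGrid(
        spot_ids=ids,
        array_coords=np.array(arr),
        pixel_coords=np.array(pix),
        in_tissue=np.ones(len(ids), dtype=bool),
        spot_diameter_px=d,
    )


def _band_labels(values: np.ndarray, n_bands: int) -> np.ndarray:
    """Partition a coordinate range into contiguous equal-width bands."""
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        raise InvalidArgumentError(
            f"cannot form {n_bands} bands along a degenerate axis"
        )
    edges = np.linspace(lo, hi, n_bands + 1)[1:-1]
    return np.searchsorted(edges, values, side="right")


def make_layered_slide(
    grid: SpotGrid,
    layers: list[LayerSpec],
    layer_axis: str = "x",
    seed: int = 0,
) -> SyntheticSlide:
    """Render a layered slide: banded texture image plus Poisson counts.

    Spots are partitioned into ``len(layers)`` contiguous bands of
    approximately equal width along ``layer_axis`` ('x' = pixel column,
    'y' = pixel row).  Each spot's square tile footprint is rendered
    with its layer's base color, stripe orientation and pixel noise;
    counts are drawn per spot and gene from Poisson(layer gene_means).
    """
    if len(layers) < 2:
        raise InvalidArgumentError("need at least 2 layers")
    if grid.n_spots == 0:
        raise InvalidArgumentError("grid is empty")
    if layer_axis not in ("x", "y"):
        raise InvalidArgumentError("layer_axis must be 'x' or 'y'")
    n_genes = len(layers[0].gene_means)
    for ls in layers:
        if len(ls.gene_means) != n_genes:
            raise InvalidArgumentError("all layers must share the gene count")

    axis_col = 1 if layer_axis == "x" else 0
    coord = grid.pixel_coords[:, axis_col]
    labels = _band_labels(coord, len(layers))
    if len(np.unique(labels)) < len(layers):
        raise InvalidArgumentError(
            f"grid too small to represent {len(layers)} bands along {layer_axis!r}"
        )

    d = grid.spot_diameter_px
    side = int(round(d))
    off = side // 2
    h = int(math.ceil(grid.pixel_coords[:, 0].max() + d)) + 1
    w = int(math.ceil(grid.pixel_coords[:, 1].max() + d)) + 1

    rng = np.random.default_rng(seed)
    image = np.full((h, w, 3), 255, dtype=np.uint8)
    for i in range(grid.n_spots):
        spec = layers[labels[i]]
        r0 = int(round(grid.pixel_coords[i, 0])) - off
        c0 = int(round(grid.pixel_coords[i, 1])) - off
        rr = np.arange(r0, r0 + side)[:, None]
        cc = np.arange(c0, c0 + side)[None, :]
        theta = math.radians(spec.texture_angle)
        phase = (rr * math.sin(theta) + cc * math.cos(theta)) / STRIPE_PERIOD_PX
        stripe = STRIPE_AMPLITUDE * np.sin(2.0 * math.pi * phase)
        tile = np.asarray(spec.color_mean, dtype=float)[None, None, :] + stripe[..., None]
        if spec.noise_sd > 0:
            tile = tile + rng.normal(0.0, spec.noise_sd, size=tile.shape)
        image[r0:r0 + side, c0:c0 + side] = np.clip(tile, 0, 255).astype(np.uint8)

    gene_means = np.stack([layers[k].gene_means for k in range(len(layers))])
    counts = rng.poisson(gene_means[labels]).astype(np.int64)

    gene_ids = [f"gene-{g:04d}" for g in range(n_genes)]
    return SyntheticSlide(
        grid=grid, image=image, counts=counts,
        truth_labels=labels.astype(int), gene_ids=gene_ids,
    )


def default_layers(
    n_layers: int,
    n_genes: int,
    baseline_mean: float = 5.0,
    marker_mean: float = 60.0,
    decay: float = 0.3,
) -> list[LayerSpec]:
    """Standard layer recipes: distinct colors/orientations, graded markers.

    Genes are split into one marker block per layer.  A block peaks at
    ``marker_mean`` in its home layer and decays geometrically (factor
    ``decay`` per layer of distance) toward ``baseline_mean`` elsewhere
    — expression transitions across histological layers are gradual,
    not step-like, so each marker's expected trajectory is strictly
    monotone in distance from its home layer.  Colors are spread over a
    fixed palette and stripe orientations over [0°, 180°).
    """
    if n_layers < 2:
        raise InvalidArgumentError("need at least 2 layers")
    palette = [
        (200, 120, 160), (120, 160, 210), (170, 200, 120),
        (210, 170, 110), (140, 120, 200), (190, 190, 140),
    ]
    per = max(n_genes // n_layers, 1)
    specs = []
    for li in range(n_layers):
        means = np.empty(n_genes)
        for g in range(n_genes):
            home = min(g // per, n_layers - 1)
            dist = abs(li - home)
            means[g] = baseline_mean + (marker_mean - baseline_mean) * decay ** dist
        specs.append(LayerSpec(
            layer_id=li,
            color_mean=palette[li % len(palette)],
            texture_angle=(180.0 / n_layers) * li,
            noise_sd=8.0,
            gene_means=means,
        ))
    return specs


def make_boundary_annotations(slide: SyntheticSlide) -> list[set[str]]:
    """One-spot-thick boundary sets between consecutive layers.

    For each adjacent layer pair ``(l, l+1)`` returns the set of layer-l
    spots that have a lattice neighbor in layer ``l+1`` — the synthetic
    stand-in for manually annotated layer boundaries.
    """
    labels = slide.truth_labels
    n_layers = slide.n_layers
    if n_layers < 2:
        raise InvalidArgumentError("slide has a single layer; no boundaries exist")
    grid = slide.grid
    label_of = {grid.spot_ids[i]: labels[i] for i in range(grid.n_spots)}
    out: list[set[str]] = []
    for lo in range(n_layers - 1):
        bound = {
            s for s in grid.spot_ids
            if label_of[s] == lo
            and any(label_of[nb] == lo + 1 for nb in grid.neighbors(s))
        }
        out.append(bound)
    return out
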