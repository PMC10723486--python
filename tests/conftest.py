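"""Shared fixtures: one synthetic 3-layer slide and one trained encoder.

Training the small encoder takes a couple of seconds, so the slide,
encoder, embeddings and a left-to-right traversal are built once per
session and shared by every test that needs a realistic alignment.
"""
from types import SimpleNamespace

import numpy as np
import pytest

import atat
from atat.fixtures import default_layers


@pytest.fixture(scope="session")
def slide3() -> atat.SyntheticSlide:
    """A 20x20 (400-spot), 3-layer, 20-gene slide with graded markers."""
    grid = atat.make_visium_grid(20, 20, 16)
    return atat.make_layered_slide(
        grid, default_layers(3, 20), layer_axis="x", seed=7
    )


@pytest.fixture(scope="session")
def trained(slide3) -> SimpleNamespace:
    """Small encoder trained on the 3-layer slide, plus its embeddings."""
    grid = slide3.grid
    tiles = atat.extract_tiles(slide3.image, grid)
    tiles_norm = atat.normalize_tiles(tiles, atat.compute_tile_stats([tiles]))
    cfg = atat.TrainConfig(epochs=20, batch_size=128, seed=1)
    encoder = atat.train_encoder(tiles_norm, grid, cfg)
    emb = atat.embed_tiles(encoder, tiles_norm)
    return SimpleNamespace(
        slide=slide3, grid=grid, tiles=tiles_norm, cfg=cfg,
        encoder=encoder, emb=emb,
    )


@pytest.fixture(scope="session")
def traversed(trained) -> SimpleNamespace:
    """A left-to-right traversal with alignment and trajectories."""
    grid = trained.grid
    left = atat.edge_spots(grid, "left")
    right = atat.edge_spots(grid, "right")
    a, b = left[len(left) // 2], right[len(right) // 2]
    graph = atat.build_graph(grid, trained.emb)
    path = atat.shortest_path(graph, a, b)
    assign = atat.assign_spots(trained.emb, path)
    counts = atat.CountMatrix(
        trained.slide.counts, list(grid.spot_ids), trained.slide.gene_ids
    )
    counts_norm = atat.normalize_counts(counts)
    traj = atat.average_along_path(counts_norm, assign)
    norm = atat.length_normalize(traj)
    return SimpleNamespace(
        graph=graph, path=path, assign=assign,
        counts_norm=counts_norm, traj=traj, norm=norm,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
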