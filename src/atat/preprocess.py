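"""Count and tile normalization.

Counts are normalized per slide the way single-cell counts usually are:
each entry is scaled so the average *total* count per spot becomes the
target ``t`` (default 1e4) and then log1p-transformed,

    X̃[s, g] = ln(1 + t · X[s, g] / (ΣX / |S|)),

where ΣX / |S| is the slide's average total count per spot.  The
transform is monotone per entry and invariant to rescaling all raw
counts by a constant.

Tiles are standardized per channel against statistics pooled over all
tiles of the dataset (optionally per slide); the statistics are kept on
the stack, and can be persisted to JSON, so the exact same transform is
applied at inference time.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .errors import DegenerateInputError, InvalidArgumentError
from .st_io import CountMatrix, TileStack

#: Default target average total count per spot.
DEFAULT_TARGET_COUNT = 1e4


def normalize_counts(counts: CountMatrix, t: float = DEFAULT_TARGET_COUNT) -> CountMatrix:
    """Log-normalize raw counts to a target average count per spot."""
    if counts.normalized:
        raise InvalidArgumentError("counts are already normalized")
    if not t > 0:
        raise InvalidArgumentError("target count t must be positive")
    X = np.asarray(counts.values, dtype=float)
    avg_per_spot = X.sum() / X.shape[0]
    if avg_per_spot == 0:
        raise DegenerateInputError(
            "all counts are zero; average count per spot is undefined"
        )
    values = np.log1p(t * X / avg_per_spot)
    return CountMatrix(
        values=values,
        spot_ids=list(counts.spot_ids),
        gene_ids=list(counts.gene_ids),
        normalized=True,
    )


@dataclass
class TileStats:
    """Per-channel mean and standard deviation over a tile dataset."""

    channel_mean: np.ndarray
    channel_sd: np.ndarray

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "channel_mean": list(map(float, self.channel_mean)),
            "channel_sd": list(map(float, self.channel_sd)),
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "TileStats":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["channel_mean"]), np.asarray(d["channel_sd"]))


def compute_tile_stats(stacks: Iterable[TileStack]) -> TileStats:
    """Pool per-channel pixel statistics over one or more slides.

    A multi-slide dataset trains a single encoder, so by default the
    statistics are pooled across every tile of every slide; pass a
    single stack for per-slide scope.
    """
    stacks = list(stacks)
    if not stacks:
        raise InvalidArgumentError("no tile stacks given")
    n_pix = sum(s.tiles[..., 0].size for s in stacks)
    mean = sum(s.tiles.reshape(-1, 3).sum(axis=0, dtype=float) for s in stacks) / n_pix
    ssq = sum(
        ((s.tiles.reshape(-1, 3) - mean) ** 2).sum(axis=0, dtype=float)
        for s in stacks
    )
    sd = np.sqrt(ssq / n_pix)
    if np.any(sd == 0):
        raise DegenerateInputError("a channel has zero variance over the dataset")
    return TileStats(channel_mean=mean, channel_sd=sd)


def normalize_tiles(tiles: TileStack, stats: TileStats | None = None) -> TileStack:
    """Standardize tiles per channel: (tile − mean_c) / sd_c.

    When ``stats`` is None they are computed from this stack alone;
    pass pooled dataset statistics (or statistics loaded from the JSON
    sidecar) to reuse the training-time transform at inference.  The
    statistics used are stored on the returned stack.
    """
    if tiles.normalized:
        raise InvalidArgumentError("tiles are already normalized")
    if stats is None:
        stats = compute_tile_stats([tiles])
    values = (tiles.tiles.astype(np.float32) - stats.channel_mean.astype(np.float32)) \
        / stats.channel_sd.astype(np.float32)
    return TileStack(
        tiles=values,
        spot_ids=list(tiles.spot_ids),
        channel_mean=np.asarray(stats.channel_mean, dtype=float),
        channel_sd=np.asarray(stats.channel_sd, dtype=float),
        normalized=True,
    )
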