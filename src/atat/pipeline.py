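"""End-to-end pipeline: learn f, build W, traverse, align, average.

One call runs the whole method on an on-disk slide bundle and writes
every artifact (encoder checkpoint, embeddings, path, assignment,
trajectory, length-normalized trajectory) plus a JSON manifest with a
SHA-256 hash per artifact, so two runs with the same config and seed
can be compared file-by-file.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alignment, embedder, preprocess, st_io, trajectory_compare, traversal
from .embedder import TrainConfig
from .errors import InvalidArgumentError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    ``start``/``end`` are anchor barcodes.  The seed feeds every
    stochastic stage (training init and triplet sampling).
    """

    bundle: str
    outdir: str
    start: str
    end: str
    target_count_t: float = preprocess.DEFAULT_TARGET_COUNT
    train: TrainConfig = field(default_factory=TrainConfig)
    spot_diameter_px: float | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        train = TrainConfig(**raw.pop("train", {}))
        return cls(train=train, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full method and return the artifact manifest."""
    bundle = Path(cfg.bundle)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    logger.info("stage=read bundle=%s", bundle)
    image, grid, counts = st_io.read_slide_bundle(
        bundle / "image.png",
        bundle / "tissue_positions.csv",
        bundle / "counts",
        spot_diameter_px=cfg.spot_diameter_px,
    )
    for anchor in (cfg.start, cfg.end):
        if anchor not in grid.spot_ids:
            raise InvalidArgumentError(f"anchor {anchor!r} is not an in-tissue spot")

    logger.info("stage=preprocess spots=%d genes=%d", counts.values.shape[0],
                counts.values.shape[1])
    counts_norm = preprocess.normalize_counts(counts, t=cfg.target_count_t)
    tiles = st_io.extract_tiles(image, grid)
    stats = preprocess.compute_tile_stats([tiles])
    tiles_norm = preprocess.normalize_tiles(tiles, stats)
    stats.to_json(outdir / "tile_stats.json")

    logger.info("stage=train encoder_size=%s epochs=%d seed=%d",
                cfg.train.encoder_size, cfg.train.epochs, cfg.train.seed)
    encoder = embedder.train_encoder(tiles_norm, grid, cfg.train)
    encoder.save(outdir / "encoder.npz")

    logger.info("stage=embed")
    emb = embedder.embed_tiles(encoder, tiles_norm)
    pd.DataFrame(emb.vectors, index=emb.spot_ids).to_csv(outdir / "embeddings.csv")

    logger.info("stage=traverse start=%s end=%s", cfg.start, cfg.end)
    graph = traversal.build_graph(grid, emb)
    path = traversal.shortest_path(graph, cfg.start, cfg.end)
    (outdir / "path.json").write_text(json.dumps(
        {"spots": path.spots, "cost": path.cost, "k": path.k}, indent=1
    ))

    logger.info("stage=align k=%d", path.k)
    assign = alignment.assign_spots(emb, path)
    pd.DataFrame({
        "barcode": assign.spot_ids, "path_index": assign.assignment,
    }).to_csv(outdir / "assignment.csv", index=False)

    logger.info("stage=trajectory")
    traj = alignment.average_along_path(counts_norm, assign)
    pd.DataFrame(traj.values, columns=traj.gene_ids).to_csv(
        outdir / "trajectory.csv", index_label="path_index"
    )
    norm = trajectory_compare.length_normalize(traj)
    pd.DataFrame(norm.values, columns=norm.gene_ids,
                 index=norm.positions).to_csv(
        outdir / "trajectory_normalized.csv", index_label="position"
    )

    artifacts = [
        "tile_stats.json", "encoder.npz", "embeddings.csv", "path.json",
        "assignment.csv", "trajectory.csv", "trajectory_normalized.csv",
    ]
    manifest = {
        "config": _jsonable(cfg.to_dict()),
        "artifacts": {a: _sha256(outdir / a) for a in artifacts},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    logger.info("stage=done artifacts=%d", len(artifacts))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
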