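"""Spatially aware tile embeddings learned with triplet loss.

The idea: tiles that are immediately adjacent on the spot lattice come
from (nearly) the same histology, while two tiles drawn at random from
the whole dataset usually do not.  Sampling triplets ⟨anchor a,
positive p, negative n⟩ accordingly and minimizing the margin loss

    L = max(0, m(f(a), f(p)) − m(f(a), f(n)) + α)

pulls same-layer tiles together and pushes different-layer tiles apart
without any labels.  The training distance m is mean squared error; the
margin α defaults to 0.001.

The encoder here is pure numpy: a fixed, seeded bank of random
convolution filters (plus per-channel intensity summaries) turns each
tile into a feature vector that preserves color and stripe/cell
orientation, and a trainable multilayer perceptron projection head —
optimized by SGD with momentum and weight decay, gradients written out
by hand — maps features to the embedding f(·) the loss acts on.
``encoder_size="small"`` (2-layer head, 32-d output) trains in seconds
on a desk CPU; ``encoder_size="full"`` uses the published training
recipe (margin 0.001, 1000 epochs, batch 768, lr 0.05, momentum 0.9,
weight decay 1e-4) and a 3-layer head with hidden dimension 2048.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import resize

from .errors import ContractError, DegenerateInputError, InvalidArgumentError
from .grids import SpotGrid
from .st_io import TileStack

logger = logging.getLogger(__name__)

# Fixed feature-bank geometry; changing any of these changes the encoder
# family, so they are module constants, not configuration.
_FEATURE_SEED = 0x5EED_F11  # seeds the frozen filter bank only
_INPUT_SIDE = 32
_N_FILTERS = 8
_FILTER_SIDE = 5
_POOL = 4


@dataclass
class TripletBatch:
    """Aligned anchor/positive/negative spot-id lists."""

    anchors: list[str]
    positives: list[str]
    negatives: list[str]

    def __post_init__(self) -> None:
        if not (len(self.anchors) == len(self.positives) == len(self.negatives)):
            raise InvalidArgumentError("triplet lists must have equal length")

    def __len__(self) -> int:
        return len(self.anchors)


@dataclass
class EmbeddingSet:
    """One embedding vector f(s) per in-tissue spot."""

    vectors: np.ndarray  # (n_spots, d)
    spot_ids: list[str]
    encoder_fingerprint: str = ""

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if not np.all(np.isfinite(self.vectors)):
            raise InvalidArgumentError("embedding vectors must be finite")
        if self.vectors.shape[0] != len(self.spot_ids):
            raise InvalidArgumentError("one vector per spot required")
        self._index = {s: i for i, s in enumerate(self.spot_ids)}

    def vector(self, spot_id: str) -> np.ndarray:
        try:
            return self.vectors[self._index[spot_id]]
        except KeyError:
            raise ContractError(f"no embedding for spot {spot_id!r}") from None

    def __contains__(self, spot_id: str) -> bool:
        return spot_id in self._index


@dataclass
class TrainConfig:
    """Hyperparameters for triplet training.

    ``margin`` is the α enforced between positive and negative pairs.
    The defaults are the desk-scale settings; :meth:`full_scale_defaults`
    returns the published full-scale recipe.
    """

    margin: float = 0.001
    epochs: int = 30
    batch_size: int = 128
    learning_rate: float = 0.05
    momentum: float = 0.9
    weight_decay: float = 1e-4
    encoder_size: str = "small"  # {"small", "full"}
    seed: int = 0
    triplets_per_epoch: int | None = None  # default: max(512, n_spots)

    def __post_init__(self) -> None:
        if not self.margin > 0:
            raise InvalidArgumentError("margin must be > 0")
        if self.epochs < 1:
            raise InvalidArgumentError("epochs must be >= 1")
        if self.encoder_size not in ("small", "full"):
            raise InvalidArgumentError("encoder_size must be 'small' or 'full'")

    @classmethod
    def full_scale_defaults(cls, seed: int = 0) -> "TrainConfig":
        """The published full-scale training configuration."""
        return cls(
            margin=0.001, epochs=1000, batch_size=768, learning_rate=0.05,
            momentum=0.9, weight_decay=1e-4, encoder_size="full", seed=seed,
        )


def sample_triplets(grid: SpotGrid, n: int, seed: int) -> TripletBatch:
    """Sample ``n`` triplets from the lattice.

    Anchors are uniform over spots that have at least one lattice
    neighbor; positives are uniform over the anchor's neighbors;
    negatives are uniform over all other spots in the dataset excluding
    the anchor and its neighbors (so a "negative" can never be a legal
    positive).  On a pooled multi-slide grid negatives may therefore
    come from a different slide than the anchor.
    """
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    ids = grid.spot_ids
    neigh = {s: sorted(grid.neighbors(s)) for s in ids}
    eligible = [
        s for s in ids
        if neigh[s] and grid.n_spots - 1 - len(neigh[s]) >= 1
    ]
    if len(ids) < 3 or not eligible:
        raise DegenerateInputError(
            "grid admits no valid triplet (need >= 3 spots and an anchor "
            "with both a neighbor and a non-neighbor)"
        )
    rng = np.random.default_rng(seed)
    anchors, positives, negatives = [], [], []
    for _ in range(n):
        a = eligible[rng.integers(len(eligible))]
        nb = neigh[a]
        p = nb[rng.integers(len(nb))]
        excluded = set(nb) | {a}
        pool = [s for s in ids if s not in excluded]
        negatives.append(pool[rng.integers(len(pool))])
        anchors.append(a)
        positives.append(p)
    return TripletBatch(anchors, positives, negatives)


def triplet_loss(d_ap: float, d_an: float, alpha: float) -> float:
    """The margin hinge max(0, d_ap − d_an + α) on precomputed distances."""
    d_ap, d_an, alpha = float(d_ap), float(d_an), float(alpha)
    if not (np.isfinite(d_ap) and np.isfinite(d_an) and np.isfinite(alpha)):
        raise InvalidArgumentError("triplet_loss inputs must be finite")
    if d_ap < 0 or d_an < 0:
        raise InvalidArgumentError("distances must be nonnegative")
    if alpha <= 0:
        raise InvalidArgumentError("margin alpha must be positive")
    return max(0.0, d_ap - d_an + alpha)


def _filter_bank() -> np.ndarray:
    rng = np.random.default_rng(_FEATURE_SEED)
    w = rng.normal(size=(_N_FILTERS, _FILTER_SIDE, _FILTER_SIDE, 3))
    w -= w.mean(axis=(1, 2, 3), keepdims=True)
    w /= np.linalg.norm(w.reshape(_N_FILTERS, -1), axis=1)[:, None, None, None]
    return w


def _tile_features(tiles: np.ndarray) -> np.ndarray:
    """Fixed convolutional features: filter-bank responses + channel stats."""
    n = tiles.shape[0]
    small = np.empty((n, _INPUT_SIDE, _INPUT_SIDE, 3), dtype=float)
    for i in range(n):
        small[i] = resize(
            tiles[i].astype(float), (_INPUT_SIDE, _INPUT_SIDE, 3),
            anti_aliasing=True, preserve_range=True,
        )
    win = np.lib.stride_tricks.sliding_window_view(
        small, (_FILTER_SIDE, _FILTER_SIDE), axis=(1, 2)
    )  # (n, 28, 28, 3, 5, 5)
    conv = np.einsum("nijcab,kabc->nkij", win, _filter_bank(), optimize=True)
    conv = np.maximum(conv, 0.0)
    m = conv.shape[-1] // _POOL  # average-pool POOL x POOL blocks
    conv = conv[:, :, : m * _POOL, : m * _POOL]
    pooled = conv.reshape(n, _N_FILTERS, m, _POOL, m, _POOL).mean(axis=(3, 5))
    flat = pooled.reshape(n, -1)
    ch_mean = tiles.mean(axis=(1, 2))
    ch_sd = tiles.std(axis=(1, 2))
    return np.concatenate([flat, ch_mean, ch_sd], axis=1)


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class TileEncoder:
    """Frozen convolutional feature bank + trainable MLP head.

    The forward map of the head defines the embedding function f used
    for graph weights and alignment.  ``fingerprint`` hashes the tile
    normalization statistics, architecture and weights, so embeddings
    can be traced to the exact encoder and preprocessing that made them.
    """

    def __init__(
        self,
        layer_dims: list[int],
        tile_channel_mean: np.ndarray,
        tile_channel_sd: np.ndarray,
        seed: int = 0,
    ) -> None:
        rng = np.random.default_rng(seed)
        self.layer_dims = list(layer_dims)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for din, dout in zip(layer_dims[:-1], layer_dims[1:]):
            self.weights.append(rng.normal(0.0, np.sqrt(2.0 / din), (din, dout)))
            self.biases.append(np.zeros(dout))
        self.tile_channel_mean = np.asarray(tile_channel_mean, dtype=float)
        self.tile_channel_sd = np.asarray(tile_channel_sd, dtype=float)
        # feature standardization over the training set; identity until fit
        self.feat_mean = np.zeros(layer_dims[0])
        self.feat_sd = np.ones(layer_dims[0])
        self.loss_history: list[float] = []

    @property
    def output_dim(self) -> int:
        return self.layer_dims[-1]

    @property
    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(np.asarray(self.layer_dims).tobytes())
        h.update(self.tile_channel_mean.tobytes())
        h.update(self.tile_channel_sd.tobytes())
        for w, b in zip(self.weights, self.biases):
            h.update(w.tobytes())
            h.update(b.tobytes())
        return h.hexdigest()[:16]

    # -- forward / backward ------------------------------------------------

    def _forward(self, feats: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        h = (feats - self.feat_mean) / self.feat_sd
        acts = [h]
        last = len(self.weights) - 1
        for li, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if li != last:
                h = _relu(h)
            acts.append(h)
        return h, acts

    def forward(self, feats: np.ndarray) -> np.ndarray:
        return self._forward(feats)[0]

    def _backward(
        self, acts: list[np.ndarray], grad_out: np.ndarray
    ) -> tuple[list[np.ndarray], list[np.ndarray]]:
        gws = [np.zeros_like(w) for w in self.weights]
        gbs = [np.zeros_like(b) for b in self.biases]
        g = grad_out
        for li in range(len(self.weights) - 1, -1, -1):
            if li != len(self.weights) - 1:
                g = g * (acts[li + 1] > 0)
            gws[li] = acts[li].T @ g
            gbs[li] = g.sum(axis=0)
            g = g @ self.weights[li].T
        return gws, gbs

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        # written with fixed zip timestamps so identical encoders produce
        # byte-identical checkpoints (np.savez stamps the current time)
        import io
        import zipfile

        arrays = {
            "feat_mean": self.feat_mean, "feat_sd": self.feat_sd,
            "tile_channel_mean": self.tile_channel_mean,
            "tile_channel_sd": self.tile_channel_sd,
            "layer_dims": np.asarray(self.layer_dims),
            "loss_history": np.asarray(self.loss_history),
        }
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"w{i}"] = w
            arrays[f"b{i}"] = b
        with zipfile.ZipFile(path, "w", zipfile.ZIP_STORED) as zf:
            for name, arr in arrays.items():
                buf = io.BytesIO()
                np.lib.format.write_array(buf, np.asarray(arr))
                info = zipfile.ZipInfo(f"{name}.npy", date_time=(1980, 1, 1, 0, 0, 0))
                zf.writestr(info, buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "TileEncoder":
        data = np.load(path)
        enc = cls(
            layer_dims=list(map(int, data["layer_dims"])),
            tile_channel_mean=data["tile_channel_mean"],
            tile_channel_sd=data["tile_channel_sd"],
        )
        enc.feat_mean = data["feat_mean"]
        enc.feat_sd = data["feat_sd"]
        enc.loss_history = list(map(float, data["loss_history"]))
        enc.weights = [data[f"w{i}"] for i in range(len(enc.layer_dims) - 1)]
        enc.biases = [data[f"b{i}"] for i in range(len(enc.layer_dims) - 1)]
        return enc


def _head_dims(encoder_size: str, feat_dim: int) -> list[int]:
    if encoder_size == "small":
        return [feat_dim, 64, 32]
    return [feat_dim, 2048, 2048, 128]


def _check_stats(tiles: TileStack, encoder: TileEncoder) -> None:
    if not tiles.normalized or tiles.channel_mean is None:
        raise InvalidArgumentError("tiles must be normalized first")
    if not (
        np.allclose(tiles.channel_mean, encoder.tile_channel_mean)
        and np.allclose(tiles.channel_sd, encoder.tile_channel_sd)
    ):
        raise ContractError(
            "tile normalization statistics do not match the statistics "
            "the encoder was trained with"
        )


def train_encoder(tiles: TileStack, grid: SpotGrid, cfg: TrainConfig) -> TileEncoder:
    """Train the embedding function f by minimizing the triplet loss.

    Each epoch draws a fresh pool of triplets from the lattice (seeded
    from ``cfg.seed`` and the epoch index) and takes minibatch SGD steps
    with momentum and weight decay.  The per-epoch mean loss is logged
    and kept on the returned encoder as ``loss_history``.
    """
    if not tiles.normalized or tiles.channel_mean is None:
        raise InvalidArgumentError("tiles must be normalized before training")
    if set(tiles.spot_ids) != set(grid.spot_ids):
        raise ContractError("tiles and grid cover different spot sets")

    feats = _tile_features(tiles.tiles)
    idx = {s: i for i, s in enumerate(tiles.spot_ids)}

    enc = TileEncoder(
        layer_dims=_head_dims(cfg.encoder_size, feats.shape[1]),
        tile_channel_mean=tiles.channel_mean,
        tile_channel_sd=tiles.channel_sd,
        seed=cfg.seed,
    )
    enc.feat_mean = feats.mean(axis=0)
    sd = feats.std(axis=0)
    enc.feat_sd = np.where(sd > 0, sd, 1.0)

    pool_size = cfg.triplets_per_epoch or max(512, grid.n_spots)
    if cfg.batch_size > pool_size:
        raise InvalidArgumentError(
            f"batch_size {cfg.batch_size} exceeds the per-epoch triplet "
            f"pool of {pool_size}"
        )

    velocity_w = [np.zeros_like(w) for w in enc.weights]
    velocity_b = [np.zeros_like(b) for b in enc.biases]
    d = enc.output_dim

    for epoch in range(cfg.epochs):
        epoch_seed = (cfg.seed * 100_003 + epoch) % (2 ** 31)
        batch_pool = sample_triplets(grid, pool_size, seed=epoch_seed)
        ai = np.array([idx[s] for s in batch_pool.anchors])
        pi = np.array([idx[s] for s in batch_pool.positives])
        ni = np.array([idx[s] for s in batch_pool.negatives])
        losses = []
        for start in range(0, pool_size - cfg.batch_size + 1, cfg.batch_size):
            sl = slice(start, start + cfg.batch_size)
            rows = np.concatenate([ai[sl], pi[sl], ni[sl]])
            out, acts = enc._forward(feats[rows])
            m = cfg.batch_size
            fa, fp, fn = out[:m], out[m:2 * m], out[2 * m:]
            d_ap = ((fa - fp) ** 2).mean(axis=1)
            d_an = ((fa - fn) ** 2).mean(axis=1)
            hinge = d_ap - d_an + cfg.margin
            active = hinge > 0
            losses.append(float(np.maximum(hinge, 0.0).mean()))
            # d m_ap/d fa = 2 (fa - fp) / d  (MSE distance over d dims)
            coef = active[:, None] * (2.0 / (d * m))
            ga = coef * ((fa - fp) - (fa - fn))
            gp = coef * (fp - fa)
            gn = coef * (fa - fn)
            grad_out = np.concatenate([ga, gp, gn])
            gws, gbs = enc._backward(acts, grad_out)
            for li in range(len(enc.weights)):
                gw = gws[li] + cfg.weight_decay * enc.weights[li]
                velocity_w[li] = cfg.momentum * velocity_w[li] - cfg.learning_rate * gw
                enc.weights[li] = enc.weights[li] + velocity_w[li]
                velocity_b[li] = cfg.momentum * velocity_b[li] - cfg.learning_rate * gbs[li]
                enc.biases[li] = enc.biases[li] + velocity_b[li]
        mean_loss = float(np.mean(losses))
        enc.loss_history.append(mean_loss)
        logger.info("epoch %d/%d: mean triplet loss %.6f", epoch + 1, cfg.epochs, mean_loss)
    return enc


def embed_tiles(encoder: TileEncoder, tiles: TileStack) -> EmbeddingSet:
    """Run the encoder in inference mode: one embedding per spot."""
    _check_stats(tiles, encoder)
    vectors = encoder.forward(_tile_features(tiles.tiles))
    return EmbeddingSet(
        vectors=vectors,
        spot_ids=list(tiles.spot_ids),
        encoder_fingerprint=encoder.fingerprint,
    )


def pool_slides(
    slides: list[tuple[SpotGrid, TileStack]],
    id_prefixes: list[str] | None = None,
) -> tuple[SpotGrid, TileStack]:
    """Concatenate several slides into one training dataset.

    Barcodes are prefixed per slide and array rows are offset so spots
    from different slides are never lattice-adjacent; triplet negatives
    sampled from the pooled grid can then come from any slide.
    """
    if not slides:
        raise InvalidArgumentError("no slides given")
    if id_prefixes is None:
        id_prefixes = [f"S{i}:" for i in range(len(slides))]
    sides = {ts.tiles.shape[1] for _, ts in slides}
    if len(sides) > 1:
        raise InvalidArgumentError("all slides must share the tile side")
    ids, arr, pix, tis, tiles = [], [], [], [], []
    row_offset = 0
    for (grid, ts), prefix in zip(slides, id_prefixes):
        order = [grid.index(s) for s in ts.spot_ids]
        ids.extend(prefix + s for s in ts.spot_ids)
        arr.append(grid.array_coords[order] + np.array([row_offset, 0]))
        pix.append(grid.pixel_coords[order])
        tis.append(grid.in_tissue[order])
        tiles.append(ts.tiles)
        row_offset += int(grid.array_coords[:, 0].max()) + 3
    pooled_grid = SpotGrid(
        spot_ids=ids,
        array_coords=np.concatenate(arr),
        pixel_coords=np.concatenate(pix),
        in_tissue=np.concatenate(tis),
        spot_diameter_px=slides[0][0].spot_diameter_px,
    )
    pooled_tiles = TileStack(
        tiles=np.concatenate(tiles), spot_ids=ids,
        normalized=all(ts.normalized for _, ts in slides),
        channel_mean=slides[0][1].channel_mean,
        channel_sd=slides[0][1].channel_sd,
    )
    return pooled_grid, pooled_tiles
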