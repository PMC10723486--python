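"""Reading and writing the standard spatial bundle, and tile extraction.

A slide bundle is the trio Space Ranger emits per capture area: the
full-resolution H&E image (PNG/TIFF), a ``tissue_positions`` table
(barcode, in_tissue, array_row, array_col, pxl_row, pxl_col), and a
spot × gene count matrix as either MatrixMarket triplets with
``barcodes.tsv``/``features.tsv`` sidecars or a dense CSV indexed by
barcode.  Readers return only in-tissue spots, ordered by ascending
``array_row`` then ``array_col``; every downstream module sees that
order.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from PIL import Image

from .errors import BoundsError, FormatError, InvalidArgumentError
from .fixtures import SyntheticSlide
from .grids import SpotGrid

__all__ = [
    "SpotGrid", "CountMatrix", "TileStack",
    "read_slide_bundle", "write_slide_bundle", "extract_tiles",
]

POSITIONS_COLUMNS = [
    "barcode", "in_tissue", "array_row", "array_col",
    "pxl_row_in_fullres", "pxl_col_in_fullres",
]


@dataclass
class CountMatrix:
    """Spot × gene expression values.

    ``normalized`` is False for raw integer counts (the matrix X) and
    True after count normalization (X-tilde).  Row order matches the
    in-tissue spot order of the paired :class:`SpotGrid`.
    """

    values: np.ndarray  # (n_spots, n_genes)
    spot_ids: list[str]
    gene_ids: list[str]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.spot_ids), len(self.gene_ids)):
            raise InvalidArgumentError("values shape does not match id lists")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise InvalidArgumentError("gene_ids are not unique")
        if not self.normalized and np.any(self.values < 0):
            raise InvalidArgumentError("raw counts must be nonnegative")


@dataclass
class TileStack:
    """Per-spot square image tiles plus dataset-level channel statistics.

    Raw stacks hold 8-bit-range float pixels; after tile normalization
    ``channel_mean``/``channel_sd`` record the statistics used so they
    can be reused at inference time.
    """

    tiles: np.ndarray  # (n_spots, side, side, 3) float32
    spot_ids: list[str]
    channel_mean: np.ndarray | None = None
    channel_sd: np.ndarray | None = None
    normalized: bool = False

    @property
    def side(self) -> int:
        return self.tiles.shape[1]


def write_slide_bundle(slide: SyntheticSlide, outdir: str | Path) -> dict[str, Path]:
    """Write a synthetic slide as a standard on-disk bundle.

    Produces ``image.png``, ``tissue_positions.csv`` (with header, Space
    Ranger column order), a ``counts/`` MatrixMarket directory
    (genes × barcodes, the Space Ranger orientation), a
    ``scalefactors_json.json`` carrying the spot diameter, and
    ``truth_labels.csv``.  Returns the path of each artifact.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = slide.grid

    image_path = outdir / "image.png"
    Image.fromarray(slide.image).save(image_path)

    positions_path = outdir / "tissue_positions.csv"
    pd.DataFrame({
        "barcode": grid.spot_ids,
        "in_tissue": grid.in_tissue.astype(int),
        "array_row": grid.array_coords[:, 0],
        "array_col": grid.array_coords[:, 1],
        "pxl_row_in_fullres": grid.pixel_coords[:, 0].astype(int),
        "pxl_col_in_fullres": grid.pixel_coords[:, 1].astype(int),
    }).to_csv(positions_path, index=False)

    counts_dir = outdir / "counts"
    counts_dir.mkdir(exist_ok=True)
    tissue_ids = [s for s, t in zip(grid.spot_ids, grid.in_tissue) if t]
    scipy.io.mmwrite(
        counts_dir / "matrix.mtx",
        scipy.sparse.csr_matrix(slide.counts.T),  # genes x barcodes
    )
    (counts_dir / "barcodes.tsv").write_text("\n".join(tissue_ids) + "\n")
    (counts_dir / "features.tsv").write_text(
        "\n".join(f"{g}\t{g}\tGene Expression" for g in slide.gene_ids) + "\n"
    )

    scale_path = outdir / "scalefactors_json.json"
    scale_path.write_text(json.dumps(
        {"spot_diameter_fullres": grid.spot_diameter_px}
    ))

    labels_path = outdir / "truth_labels.csv"
    pd.DataFrame({
        "barcode": tissue_ids,
        "layer": [slide.truth_labels[i] for i, t in enumerate(grid.in_tissue) if t],
    }).to_csv(labels_path, index=False)

    return {
        "image": image_path,
        "positions": positions_path,
        "counts": counts_dir,
        "scalefactors": scale_path,
        "truth_labels": labels_path,
    }


def _read_positions(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
    has_header = "barcode" in first.lower()
    if has_header:
        df = pd.read_csv(path)
        df.columns = [c.strip().lower() for c in df.columns]
        rename = {"pxl_row": "pxl_row_in_fullres", "pxl_col": "pxl_col_in_fullres"}
        df = df.rename(columns=rename)
    else:
        df = pd.read_csv(path, header=None, names=POSITIONS_COLUMNS)
    missing = [c for c in POSITIONS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"positions file {path} lacks columns {missing}")
    return df


def _read_counts(path: Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Return (spots × genes values, barcodes, gene ids)."""
    path = Path(path)
    if path.is_dir():
        mtx = None
        for name in ("matrix.mtx", "matrix.mtx.gz"):
            if (path / name).exists():
                mtx = path / name
                break
        if mtx is None:
            raise FormatError(f"no matrix.mtx found under {path}")
        barcodes = (path / "barcodes.tsv").read_text().split()
        features = [
            line.split("\t")[0]
            for line in (path / "features.tsv").read_text().splitlines()
            if line.strip()
        ]
        m = scipy.io.mmread(mtx)
        m = np.asarray(m.todense()) if scipy.sparse.issparse(m) else np.asarray(m)
        if m.shape == (len(features), len(barcodes)):
            m = m.T
        elif m.shape != (len(barcodes), len(features)):
            raise FormatError(
                f"matrix shape {m.shape} reconciles with neither "
                f"{len(barcodes)} barcodes nor {len(features)} features"
            )
        return m, barcodes, features
    # dense CSV, barcode index in the first column, genes as columns
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(), [str(b) for b in df.index], [str(g) for g in df.columns]


def _check_footprints(image: np.ndarray, grid: SpotGrid) -> None:
    side = int(round(grid.spot_diameter_px))
    off = side // 2
    bad = []
    for i, s in enumerate(grid.spot_ids):
        r0 = int(round(grid.pixel_coords[i, 0])) - off
        c0 = int(round(grid.pixel_coords[i, 1])) - off
        if r0 < 0 or c0 < 0 or r0 + side > image.shape[0] or c0 + side > image.shape[1]:
            bad.append(s)
    if bad:
        raise BoundsError(
            f"tile footprints fall outside the image for spots: {bad[:10]}"
            + ("..." if len(bad) > 10 else "")
        )


def read_slide_bundle(
    image_path: str | Path,
    positions_path: str | Path,
    counts_path: str | Path,
    spot_diameter_px: float | None = None,
) -> tuple[np.ndarray, SpotGrid, CountMatrix]:
    """Load an on-disk slide bundle.

    If ``spot_diameter_px`` is omitted, a ``scalefactors_json.json``
    next to the positions file supplies it.  Only in-tissue spots are
    returned, sorted ascending by (array_row, array_col), with count
    rows reordered to match; out-of-tissue spots are dropped here and
    never seen downstream.
    """
    image = np.asarray(Image.open(image_path).convert("RGB"))
    positions = _read_positions(Path(positions_path))
    values, barcodes, gene_ids = _read_counts(Path(counts_path))

    if spot_diameter_px is None:
        scale = Path(positions_path).parent / "scalefactors_json.json"
        if not scale.exists():
            raise InvalidArgumentError(
                "spot_diameter_px not given and no scalefactors_json.json found"
            )
        spot_diameter_px = float(json.loads(scale.read_text())["spot_diameter_fullres"])

    tissue = positions[positions["in_tissue"].astype(int) == 1].copy()
    tissue = tissue.sort_values(["array_row", "array_col"], kind="stable")

    pos_set = set(tissue["barcode"].astype(str))
    cnt_set = set(barcodes)
    if pos_set != cnt_set:
        only_pos = sorted(pos_set - cnt_set)[:10]
        only_cnt = sorted(cnt_set - pos_set)[:10]
        raise FormatError(
            "positions and counts barcodes do not reconcile; "
            f"only in positions: {only_pos}; only in counts: {only_cnt}"
        )

    order = [barcodes.index(b) for b in tissue["barcode"].astype(str)]
    counts = CountMatrix(
        values=np.asarray(values)[order],
        spot_ids=list(tissue["barcode"].astype(str)),
        gene_ids=gene_ids,
        normalized=False,
    )
    grid = SpotGrid(
        spot_ids=list(tissue["barcode"].astype(str)),
        array_coords=tissue[["array_row", "array_col"]].to_numpy(int),
        pixel_coords=tissue[["pxl_row_in_fullres", "pxl_col_in_fullres"]].to_numpy(float),
        in_tissue=np.ones(len(tissue), dtype=bool),
        spot_diameter_px=float(spot_diameter_px),
    )
    _check_footprints(image, grid)
    return image, grid, counts


def extract_tiles(image: np.ndarray, grid: SpotGrid) -> TileStack:
    """Cut one square tile per in-tissue spot, centered on the spot.

    Tile side is ``round(spot_diameter_px)``; the top-left corner sits
    ``floor(side/2)`` pixels up and left of the spot center, so
    extraction is bit-reproducible for odd diameters too.
    """
    image = np.asarray(image)
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    _check_footprints(image, grid)
    side = int(round(grid.spot_diameter_px))
    off = side // 2
    keep = np.flatnonzero(grid.in_tissue)
    tiles = np.empty((len(keep), side, side, 3), dtype=np.float32)
    ids = []
    for k, i in enumerate(keep):
        r0 = int(round(grid.pixel_coords[i, 0])) - off
        c0 = int(round(grid.pixel_coords[i, 1])) - off
        tiles[k] = image[r0:r0 + side, c0:c0 + side, :3]
        ids.append(grid.spot_ids[i])
    return TileStack(tiles=tiles, spot_ids=ids, normalized=False)
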