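"""The hexagonal spot lattice.

10x Visium arranges capture spots on a hexagonal lattice.  In array
coordinates a spot sits at integer ``(array_row, array_col)`` where row
``r`` only holds columns with parity ``r mod 2``; the six lattice
neighbors of a spot are at array offsets ``(0, ±2)`` and ``(±1, ±1)``.
:class:`SpotGrid` is the in-memory form of a Space Ranger style
``tissue_positions`` table plus the spot diameter, and is the container
every other module consumes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

#: Array-coordinate offsets of the six hexagonal lattice neighbors.
HEX_OFFSETS: tuple[tuple[int, int], ...] = (
    (0, 2), (0, -2), (1, 1), (1, -1), (-1, 1), (-1, -1),
)


@dataclass
class SpotGrid:
    """Spot identities and geometry of one slide.

    Parameters
    ----------
    spot_ids
        Unique barcodes, one per spot, in a stable order (ascending
        ``array_row`` then ``array_col`` when produced by this package).
    array_coords
        ``(n, 2)`` integer array of ``(array_row, array_col)``.
    pixel_coords
        ``(n, 2)`` array of ``(row, col)`` centers in full-resolution
        image pixels, 0-based, matching numpy image indexing.
    in_tissue
        Boolean flag per spot.
    spot_diameter_px
        Spot (and tile) diameter in pixels; must be positive.
    """

    spot_ids: list[str]
    array_coords: np.ndarray
    pixel_coords: np.ndarray
    in_tissue: np.ndarray
    spot_diameter_px: float

    _index: dict[str, int] = field(init=False, repr=False)
    _coord_index: dict[tuple[int, int], int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.array_coords = np.asarray(self.array_coords, dtype=int)
        self.pixel_coords = np.asarray(self.pixel_coords, dtype=float)
        self.in_tissue = np.asarray(self.in_tissue, dtype=bool)
        n = len(self.spot_ids)
        if len(set(self.spot_ids)) != n:
            raise InvalidArgumentError("spot_ids are not unique")
        if self.array_coords.shape != (n, 2) or self.pixel_coords.shape != (n, 2):
            raise InvalidArgumentError("coordinate arrays must have shape (n, 2)")
        if self.in_tissue.shape != (n,):
            raise InvalidArgumentError("in_tissue must have shape (n,)")
        if not self.spot_diameter_px > 0:
            raise InvalidArgumentError("spot_diameter_px must be positive")
        self._coord_index = {}
        for i, (r, c) in enumerate(map(tuple, self.array_coords)):
            if (r, c) in self._coord_index:
                raise InvalidArgumentError(f"duplicate array coordinate ({r}, {c})")
            self._coord_index[(r, c)] = i
        self._index = {s: i for i, s in enumerate(self.spot_ids)}

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    def index(self, spot_id: str) -> int:
        try:
            return self._index[spot_id]
        except KeyError:
            raise InvalidArgumentError(f"unknown spot {spot_id!r}") from None

    def neighbors(self, spot_id: str) -> set[str]:
        """In-tissue lattice neighbors of ``spot_id`` (at most six)."""
        i = self.index(spot_id)
        r, c = self.array_coords[i]
        out: set[str] = set()
        for dr, dc in HEX_OFFSETS:
            j = self._coord_index.get((r + dr, c + dc))
            if j is not None and self.in_tissue[j]:
                out.add(self.spot_ids[j])
        return out

    def tissue_subset(self) -> "SpotGrid":
        """A grid containing only the in-tissue spots, original order."""
        keep = np.flatnonzero(self.in_tissue)
        return SpotGrid(
            spot_ids=[self.spot_ids[i] for i in keep],
            array_coords=self.array_coords[keep],
            pixel_coords=self.pixel_coords[keep],
            in_tissue=self.in_tissue[keep],
            spot_diameter_px=self.spot_diameter_px,
        )
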