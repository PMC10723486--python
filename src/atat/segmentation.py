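"""Quantizing an alignment into discrete tissue layers.

Annotated layer boundaries (ordered spot sets B_1 … B_{L−1}, each a
one-spot-thick band of lower-layer spots facing the next layer) act as
an oracle: walking the traversed path from start to end, the first
path index c_l whose spot lies on boundary B_l closes layer l−1, so
layer l covers path indices c_l < p ≤ c_{l+1} — the crossing tile
itself belongs to the lower layer, consistent with the boundary spots
being lower-layer tissue.  Layer l is then the union of the assignment
sets of all path tiles in its run, S_l = ∪ S_p, which labels every
spot on the slide.  Agreement between two labelings is scored with the
Adjusted Rand Index.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .alignment import AssignmentMap
from .errors import AnnotationError, ContractError, InvalidArgumentError


@dataclass
class BoundaryAnnotation:
    """Ordered boundary spot sets, start-anchor side first."""

    boundaries: list[set[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for b in self.boundaries:
            if seen & b:
                raise InvalidArgumentError("boundary sets must be disjoint")
            seen |= b

    @property
    def n_layers(self) -> int:
        return len(self.boundaries) + 1


@dataclass
class SegmentLabels:
    """Per-spot integer layer label in 0..L−1."""

    spot_ids: list[str]
    labels: np.ndarray
    n_layers: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.spot_ids),):
            raise InvalidArgumentError("one label per spot required")
        if len(self.labels) and (
            self.labels.min() < 0 or self.labels.max() >= self.n_layers
        ):
            raise InvalidArgumentError("labels outside 0..L-1")


def segment_from_path(
    assign: AssignmentMap, bounds: BoundaryAnnotation
) -> SegmentLabels:
    """Split the path at its first crossing of each boundary and label
    every spot by the run of its assigned path tile.

    Only first crossings count; crossings must occur in annotation
    order, else the annotation does not match the traversal direction.
    The crossing tile closes the layer being left (it lies on the
    lower-layer side of the boundary); the next tile opens the next
    layer.
    """
    path = assign.path
    crossings: list[int] = []
    for li, boundary in enumerate(bounds.boundaries):
        hit = [i for i, s in enumerate(path.spots) if s in boundary]
        if not hit:
            raise AnnotationError(
                f"path never crosses boundary {li} "
                f"(between layers {li} and {li + 1})"
            )
        crossings.append(min(hit))
    for prev, cur in zip(crossings, crossings[1:]):
        if cur <= prev:
            raise AnnotationError(
                "boundaries are crossed out of order along the path; "
                "check the annotation order against the traversal direction"
            )
    # run of each path index: number of crossing indices strictly < i,
    # so each crossing tile stays with the layer it closes
    cuts = np.asarray(crossings)
    runs = np.searchsorted(cuts, np.arange(path.k), side="left")
    labels = runs[assign.assignment]
    return SegmentLabels(
        spot_ids=list(assign.spot_ids),
        labels=labels,
        n_layers=bounds.n_layers,
    )


def adjusted_rand_index(labels_a: SegmentLabels, labels_b: SegmentLabels) -> float:
    """Chance-corrected agreement between two labelings of the same spots.

    Standard permutation-model ARI from the contingency table; 1 for
    identical partitions (up to label renaming), ~0 for independent
    ones, negative for worse-than-chance agreement.
    """
    if set(labels_a.spot_ids) != set(labels_b.spot_ids):
        raise ContractError("labelings cover different spot sets")
    order = {s: i for i, s in enumerate(labels_b.spot_ids)}
    b_aligned = labels_b.labels[[order[s] for s in labels_a.spot_ids]]
    return float(adjusted_rand_score(labels_a.labels, b_aligned))
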