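"""Projecting the whole slide onto the traversed path.

Every in-tissue spot s is assigned to the path tile p whose embedding
is nearest in Euclidean distance,

    C(s) = argmin_{p ∈ P*} ‖f(s) − f(p)‖₂,

so the assignment sets S_p = {s | C(s) = p} partition the slide, and
averaging normalized expression within each S_p turns the 2-D slide
into 1-D per-gene trajectories X̂ along the path.  The module also
adapts external per-spot scalar depths (as produced by
expression-based aligners) into the same assignment structure by
rounding depths to integer levels.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .embedder import EmbeddingSet
from .errors import ContractError, InvalidArgumentError
from .st_io import CountMatrix
from .traversal import TraversalPath


@dataclass
class AssignmentMap:
    """Per-spot index into the path; the S_p sets read off from it."""

    spot_ids: list[str]
    assignment: np.ndarray  # (n_spots,) int, values in 0..k-1
    path: TraversalPath

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        if self.assignment.shape != (len(self.spot_ids),):
            raise InvalidArgumentError("one assignment per spot required")
        if self.assignment.min(initial=0) < 0 or (
            len(self.assignment) and self.assignment.max() >= self.path.k
        ):
            raise InvalidArgumentError("assignment indices outside the path")

    def sets(self) -> list[list[str]]:
        """The assignment sets S_p, ordered along the path."""
        out: list[list[str]] = [[] for _ in range(self.path.k)]
        for s, p in zip(self.spot_ids, self.assignment):
            out[p].append(s)
        return out


@dataclass
class TrajectoryMatrix:
    """Path-aligned expression X̂: one row per path tile, ordered a→b."""

    values: np.ndarray  # (k, n_genes)
    path: TraversalPath
    gene_ids: list[str]
    set_sizes: np.ndarray  # (k,) int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.set_sizes = np.asarray(self.set_sizes, dtype=int)
        if self.values.shape != (self.path.k, len(self.gene_ids)):
            raise InvalidArgumentError("values must be (k, n_genes)")
        if self.set_sizes.shape != (self.path.k,):
            raise InvalidArgumentError("one set size per path tile required")


def assign_spots(emb: EmbeddingSet, path: TraversalPath) -> AssignmentMap:
    """Assign every spot to its nearest path tile in embedding space.

    Ties go to the smallest path index (earliest along the traversal),
    which also keeps a path spot with a duplicated embedding on the
    earliest of the duplicates.
    """
    if path.k == 0:
        raise InvalidArgumentError("path is empty")
    for p in path.spots:
        if p not in emb:
            raise ContractError(f"no embedding for path spot {p!r}")
    path_vecs = np.stack([emb.vector(p) for p in path.spots])
    d = cdist(emb.vectors, path_vecs)  # (n_spots, k)
    assignment = d.argmin(axis=1)  # argmin returns the first (smallest) index
    return AssignmentMap(
        spot_ids=list(emb.spot_ids), assignment=assignment, path=path
    )


def average_along_path(
    counts_norm: CountMatrix, assign: AssignmentMap
) -> TrajectoryMatrix:
    """Average normalized expression within each assignment set:
    X̂[p, g] = mean over s ∈ S_p of X̃[s, g]."""
    if not counts_norm.normalized:
        raise InvalidArgumentError("counts must be normalized before averaging")
    if set(counts_norm.spot_ids) != set(assign.spot_ids):
        raise ContractError("counts and assignment cover different spot sets")
    k = assign.path.k
    order = {s: i for i, s in enumerate(counts_norm.spot_ids)}
    rows = np.array([order[s] for s in assign.spot_ids])
    X = np.asarray(counts_norm.values, dtype=float)[rows]
    sums = np.zeros((k, X.shape[1]))
    np.add.at(sums, assign.assignment, X)
    sizes = np.bincount(assign.assignment, minlength=k)
    if np.any(sizes == 0):  # cannot happen: each path spot is its own member
        raise ContractError("empty assignment set")
    return TrajectoryMatrix(
        values=sums / sizes[:, None],
        path=assign.path,
        gene_ids=list(counts_norm.gene_ids),
        set_sizes=sizes,
    )


@dataclass
class DepthAssignment:
    """Integer depth levels adapted from an external per-spot scalar depth."""

    spot_ids: list[str]
    levels: np.ndarray  # consecutive integers 0..k-1, order-preserving
    k: int


def depths_to_assignments(
    depths: np.ndarray, spot_ids: list[str] | None = None
) -> DepthAssignment:
    """Round external scalar depths to integer levels: C(s) = round(d_s).

    Rounding is half-away-from-zero; the unique rounded depths are then
    re-indexed to consecutive integers 0..k−1 preserving their order,
    so the result plugs into the same trajectory machinery as a path
    assignment.
    """
    depths = np.asarray(depths, dtype=float)
    if not np.all(np.isfinite(depths)):
        raise InvalidArgumentError("depths must be finite")
    if spot_ids is None:
        spot_ids = [f"spot{i}" for i in range(len(depths))]
    rounded = (np.sign(depths) * np.floor(np.abs(depths) + 0.5)).astype(int)
    uniq = np.unique(rounded)  # sorted ascending
    remap = {v: i for i, v in enumerate(uniq)}
    levels = np.array([remap[v] for v in rounded], dtype=int)
    return DepthAssignment(spot_ids=list(spot_ids), levels=levels, k=len(uniq))


def average_by_levels(
    counts_norm: CountMatrix, depth_assign: DepthAssignment
) -> np.ndarray:
    """Average normalized expression within each depth level.

    Returns a (k, n_genes) matrix, the depth-aligner analogue of X̂,
    assuming levels are linearly spaced along the tissue axis.
    """
    if not counts_norm.normalized:
        raise InvalidArgumentError("counts must be normalized before averaging")
    if set(counts_norm.spot_ids) != set(depth_assign.spot_ids):
        raise ContractError("counts and depth assignment cover different spot sets")
    order = {s: i for i, s in enumerate(counts_norm.spot_ids)}
    rows = np.array([order[s] for s in depth_assign.spot_ids])
    X = np.asarray(counts_norm.values, dtype=float)[rows]
    sums = np.zeros((depth_assign.k, X.shape[1]))
    np.add.at(sums, depth_assign.levels, X)
    sizes = np.bincount(depth_assign.levels, minlength=depth_assign.k)
    if np.any(sizes == 0):
        raise ContractError("a depth level has no spots")
    return sums / sizes[:, None]
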