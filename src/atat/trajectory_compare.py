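"""Length normalization and cross-sample trajectory comparison.

Paths through different samples (or between different anchor pairs)
have different lengths k, so raw trajectories X̂ are not directly
comparable.  Mapping path index i to relative position i/(k−1) puts
every path on [0, 1]; linear interpolation at the 101 grid positions
0.00, 0.01, …, 1.00 then yields a length-normalized matrix X̄ of shape
(101, |G|) whose rows line up across samples.  Normalized trajectories
can be averaged with a 95% confidence band, and concordance between
two trajectories is quantified by Spearman's rank correlation ρ.

The module also implements "reasonable" start/end pair sampling for
the anchor-invariance evaluation: given user-supplied ordered edge
spot lists A (starts) and B (ends), each start aᵢ is paired with the
ends within a window of radius r (default 15) around its
position-matched end, and pairs are sampled without replacement.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .alignment import TrajectoryMatrix
from .errors import (
    ContractError,
    DegenerateInputError,
    InvalidArgumentError,
    UndefinedCorrelationError,
)
from .grids import SpotGrid

#: Number of relative positions on [0, 1] (every 0.01).
N_POSITIONS = 101
#: Default window radius for reasonable end-spot pairing.
DEFAULT_PAIR_RADIUS = 15


@dataclass
class NormalizedTrajectory:
    """X̄: expression sampled at 101 relative positions on [0, 1]."""

    values: np.ndarray  # (101, n_genes)
    gene_ids: list[str]
    source: str = ""  # identifier of the originating path

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_POSITIONS, len(self.gene_ids)):
            raise InvalidArgumentError(
                f"values must have shape ({N_POSITIONS}, n_genes)"
            )

    @property
    def positions(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, N_POSITIONS)

    def gene(self, gene_id: str) -> np.ndarray:
        try:
            return self.values[:, self.gene_ids.index(gene_id)]
        except ValueError:
            raise InvalidArgumentError(f"unknown gene {gene_id!r}") from None


def length_normalize(traj: TrajectoryMatrix) -> NormalizedTrajectory:
    """Resample a k-row trajectory onto the 101-position relative grid.

    Path index i maps to position i/(k−1) — start 0, end 1 — and each
    gene is linearly interpolated in between; endpoints are preserved
    exactly.  Uniform index spacing is used (k reflects the sampling
    rate of the trajectory); spacing proportional to cumulative edge
    weight is available via ``length_normalize_weighted``.
    """
    k = traj.values.shape[0]
    if k < 2:
        raise DegenerateInputError("cannot length-normalize a path of one spot")
    src_pos = np.arange(k) / (k - 1)
    return _interp_at(traj, src_pos)


def length_normalize_weighted(
    traj: TrajectoryMatrix, edge_weights: np.ndarray
) -> NormalizedTrajectory:
    """Length normalization with positions proportional to cumulative
    edge weight rather than path index."""
    k = traj.values.shape[0]
    if k < 2:
        raise DegenerateInputError("cannot length-normalize a path of one spot")
    edge_weights = np.asarray(edge_weights, dtype=float)
    if edge_weights.shape != (k - 1,) or np.any(edge_weights < 0):
        raise InvalidArgumentError("need k-1 nonnegative edge weights")
    cum = np.concatenate([[0.0], np.cumsum(edge_weights)])
    if cum[-1] == 0:
        raise DegenerateInputError("total path weight is zero")
    return _interp_at(traj, cum / cum[-1])


def _interp_at(traj: TrajectoryMatrix, src_pos: np.ndarray) -> NormalizedTrajectory:
    grid = np.linspace(0.0, 1.0, N_POSITIONS)
    out = np.empty((N_POSITIONS, traj.values.shape[1]))
    for g in range(traj.values.shape[1]):
        out[:, g] = np.interp(grid, src_pos, traj.values[:, g])
    out[0] = traj.values[0]
    out[-1] = traj.values[-1]
    return NormalizedTrajectory(
        values=out,
        gene_ids=list(traj.gene_ids),
        source="->".join([traj.path.spots[0], traj.path.spots[-1]]),
    )


@dataclass
class TrajectorySummary:
    """Per-position, per-gene mean with a 95% confidence band.

    For n = 1 the sample standard deviation is undefined and the band
    is omitted (``sd``, ``ci_low``, ``ci_high`` are None).
    """

    mean: np.ndarray
    sd: np.ndarray | None
    ci_low: np.ndarray | None
    ci_high: np.ndarray | None
    n: int
    gene_ids: list[str]


def average_trajectories(trajs: list[NormalizedTrajectory]) -> TrajectorySummary:
    """Mean trajectory with normal-approximation 95% CI
    (mean ± 1.96·sd/√n)."""
    if not trajs:
        raise InvalidArgumentError("no trajectories given")
    genes = trajs[0].gene_ids
    for t in trajs[1:]:
        if t.gene_ids != genes:
            raise ContractError("trajectories have mismatched gene sets")
    stack = np.stack([t.values for t in trajs])
    mean = stack.mean(axis=0)
    n = len(trajs)
    if n == 1:
        return TrajectorySummary(mean, None, None, None, n, list(genes))
    sd = stack.std(axis=0, ddof=1)
    half = 1.96 * sd / np.sqrt(n)
    return TrajectorySummary(mean, sd, mean - half, mean + half, n, list(genes))


def edge_spots(grid: SpotGrid, side: str) -> list[str]:
    """Convenience edge extraction for band-layered rectangular slides:
    the leftmost ('left') or rightmost ('right') in-tissue spot of each
    array row, ordered by row.  Real tissue edges are irregular and are
    normally supplied by the user; this helper covers the common case
    of layers stacked along x with the outer layers at the slide sides.
    """
    if side not in ("left", "right"):
        raise InvalidArgumentError("side must be 'left' or 'right'")
    rows: dict[int, str] = {}
    for i, s in enumerate(grid.spot_ids):
        if not grid.in_tissue[i]:
            continue
        r = int(grid.array_coords[i, 0])
        x = grid.pixel_coords[i, 1]
        cur = rows.get(r)
        if cur is None or (side == "left") == (x < grid.pixel_coords[grid.index(cur), 1]):
            rows[r] = s
    return [rows[r] for r in sorted(rows)]


@dataclass
class PairPool:
    """All reasonable (start, end) anchor pairs Z under the window rule."""

    starts: list[str]
    ends: list[str]
    radius: int
    pairs: list[tuple[str, str]]

    def __len__(self) -> int:
        return len(self.pairs)


def build_pair_pool(
    grid: SpotGrid,
    start_edge: list[str],
    end_edge: list[str],
    r: int = DEFAULT_PAIR_RADIUS,
) -> PairPool:
    """Enumerate reasonable start/end pairs Z.

    Edges are sorted ascending by the y pixel coordinate (image row).
    Start aᵢ is paired with every end b_j with
    j ∈ [max(i−r, 0), min(i+r+1, |B|)); when |A| ≠ |B| the window is
    centered on the proportionally scaled position
    round(i·(|B|−1)/(|A|−1)).
    """
    if not start_edge or not end_edge:
        raise InvalidArgumentError("start and end edges must be non-empty")
    if r < 0:
        raise InvalidArgumentError("radius must be >= 0")

    def sort_by_y(edge: list[str]) -> list[str]:
        return sorted(edge, key=lambda s: (grid.pixel_coords[grid.index(s)][0], s))

    A, B = sort_by_y(start_edge), sort_by_y(end_edge)
    pairs: list[tuple[str, str]] = []
    for i, a in enumerate(A):
        if len(A) == len(B):
            center = i
        elif len(A) == 1:
            center = 0
        else:
            center = round(i * (len(B) - 1) / (len(A) - 1))
        for j in range(max(center - r, 0), min(center + r + 1, len(B))):
            pairs.append((a, B[j]))
    return PairPool(starts=A, ends=B, radius=r, pairs=pairs)


def sample_pairs(pool: PairPool, n: int = 100, seed: int = 0) -> list[tuple[str, str]]:
    """Uniformly sample ``n`` distinct pairs from Z without replacement."""
    if len(pool) < n:
        raise InvalidArgumentError(
            f"pool holds only {len(pool)} pairs; cannot sample {n}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool.pairs[i] for i in idx]


def spearman_concordance(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman's ρ between two trajectory columns (average-rank ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidArgumentError("inputs must be 1-D of equal length")
    if len(x) < 3:
        raise InvalidArgumentError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            "rank correlation is undefined for a constant input"
        )
    rho, _ = stats.spearmanr(x, y)
    return float(rho)
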