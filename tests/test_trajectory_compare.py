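"""Length normalization, trajectory averaging, pair sampling, Spearman."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import atat
from atat.errors import (
    ContractError,
    DegenerateInputError,
    InvalidArgumentError,
    UndefinedCorrelationError,
)


def traj_of(values, gene_ids=None):
    values = np.asarray(values, dtype=float)
    ids = [f"s{i}" for i in range(values.shape[0])]
    return atat.TrajectoryMatrix(
        values=values,
        path=atat.TraversalPath(spots=ids, cost=1.0),
        gene_ids=gene_ids or [f"g{j}" for j in range(values.shape[1])],
        set_sizes=np.ones(values.shape[0], dtype=int),
    )


def norm_of(values, gene_ids=None):
    values = np.asarray(values, dtype=float)
    return atat.NormalizedTrajectory(
        values=values,
        gene_ids=gene_ids or [f"g{j}" for j in range(values.shape[1])],
    )


class TestLengthNormalize:
    def test_101_position_rows(self, traversed):
        assert traversed.norm.values.shape == (101, 20)

    def test_constant_trajectory_stays_constant(self):
        out = atat.length_normalize(traj_of(np.full((5, 2), 1.25)))
        assert np.all(out.values == 1.25)

    def test_piecewise_linear_interpolation_by_hand(self):
        # k=3, values (0, 1, 0): position 0.25 is halfway up the ramp
        out = atat.length_normalize(traj_of([[0.0], [1.0], [0.0]]))
        i = 25
        assert out.positions[i] == pytest.approx(0.25)
        assert out.values[i, 0] == pytest.approx(0.5)

    def test_endpoints_equal_path_endpoints_exactly(self, traversed):
        np.testing.assert_array_equal(
            traversed.norm.values[0], traversed.traj.values[0]
        )
        np.testing.assert_array_equal(
            traversed.norm.values[-1], traversed.traj.values[-1]
        )

    def test_single_spot_path_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            atat.length_normalize(traj_of([[1.0]]))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(k=st.integers(2, 30), seed=st.integers(0, 1000))
    def test_interpolation_stays_within_source_bounds(self, k, seed):
        vals = np.random.default_rng(seed).normal(size=(k, 3))
        out = atat.length_normalize(traj_of(vals))
        assert np.all(out.values >= vals.min(axis=0) - 1e-12)
        assert np.all(out.values <= vals.max(axis=0) + 1e-12)

    def test_weighted_spacing_option(self):
        # all weight on the first edge: the ramp is traversed early
        out = atat.length_normalize_weighted(
            traj_of([[0.0], [1.0], [2.0]]), edge_weights=np.array([3.0, 1.0])
        )
        assert out.values[75, 0] == pytest.approx(1.0)  # position 0.75 = row 1


class TestAverageTrajectories:
    def test_single_trajectory_mean_no_band(self):
        t = norm_of(np.random.default_rng(0).normal(size=(101, 2)))
        s = atat.average_trajectories([t])
        np.testing.assert_array_equal(s.mean, t.values)
        assert s.sd is None and s.ci_low is None and s.ci_high is None

    def test_opposite_trajectories_average_to_zero(self):
        v = np.random.default_rng(1).normal(size=(101, 2))
        s = atat.average_trajectories([norm_of(v), norm_of(-v)])
        np.testing.assert_allclose(s.mean, 0.0, atol=1e-12)

    def test_three_constants_hand_statistics(self):
        s = atat.average_trajectories(
            [norm_of(np.full((101, 1), c)) for c in (1.0, 2.0, 3.0)]
        )
        assert np.all(s.mean == 2.0)
        np.testing.assert_allclose(s.sd, 1.0)
        np.testing.assert_allclose(s.ci_high - s.mean, 1.96 / np.sqrt(3))

    def test_gene_set_mismatch_rejected(self):
        a = norm_of(np.zeros((101, 1)), ["g0"])
        b = norm_of(np.zeros((101, 1)), ["other"])
        with pytest.raises(ContractError):
            atat.average_trajectories([a, b])


class TestPairPool:
    def test_single_spot_edges(self, slide3):
        grid = slide3.grid
        pool = atat.build_pair_pool(
            grid, [grid.spot_ids[0]], [grid.spot_ids[-1]], r=15
        )
        assert pool.pairs == [(grid.spot_ids[0], grid.spot_ids[-1])]

    def test_window_count_five_by_five_radius_one(self, slide3):
        grid = slide3.grid
        col0 = [s for i, s in enumerate(grid.spot_ids)
                if grid.array_coords[i][1] in (0, 1)][:5]
        last = 2 * 19  # max even array col
        colN = [s for i, s in enumerate(grid.spot_ids)
                if grid.array_coords[i][1] in (last, last + 1)][:5]
        pool = atat.build_pair_pool(grid, col0, colN, r=1)
        assert len(pool) == 13  # windows of size 2,3,3,3,2

    def test_radius_saturates_to_full_product(self, slide3):
        grid = slide3.grid
        A = grid.spot_ids[:4]
        B = grid.spot_ids[-4:]
        pool = atat.build_pair_pool(grid, A, B, r=10)
        assert len(pool) == 16
        assert all(len([p for p in pool.pairs if p[0] == a]) <= 2 * 10 + 1
                   for a in A)

    def test_empty_edge_rejected(self, slide3):
        with pytest.raises(InvalidArgumentError):
            atat.build_pair_pool(slide3.grid, [], slide3.grid.spot_ids[:2])

    def test_starts_sorted_by_y(self, slide3):
        grid = slide3.grid
        A = list(reversed(grid.spot_ids[:6]))
        pool = atat.build_pair_pool(grid, A, grid.spot_ids[-6:], r=2)
        ys = [grid.pixel_coords[grid.index(s)][0] for s in pool.starts]
        assert ys == sorted(ys)


class TestSamplePairs:
    def make_pool(self, slide3, r=10):
        grid = slide3.grid
        return atat.build_pair_pool(
            grid, grid.spot_ids[:8], grid.spot_ids[-8:], r=r
        )

    def test_exhaustive_sample_is_permutation(self, slide3):
        pool = self.make_pool(slide3)
        out = atat.sample_pairs(pool, n=len(pool), seed=0)
        assert sorted(out) == sorted(pool.pairs)

    def test_deterministic_given_seed(self, slide3):
        pool = self.make_pool(slide3)
        assert atat.sample_pairs(pool, 10, seed=3) == \
            atat.sample_pairs(pool, 10, seed=3)

    def test_distinct_members_of_pool(self, slide3):
        pool = self.make_pool(slide3)
        out = atat.sample_pairs(pool, n=20, seed=1)
        assert len(set(out)) == 20
        assert all(p in pool.pairs for p in out)

    def test_oversampling_rejected(self, slide3):
        pool = self.make_pool(slide3, r=0)
        with pytest.raises(InvalidArgumentError, match=str(len(pool))):
            atat.sample_pairs(pool, n=len(pool) + 1, seed=0)


class TestSpearman:
    def test_identity_and_reversal(self):
        x = np.array([0.3, 1.0, 2.0, 5.0, 9.0])
        assert atat.spearman_concordance(x, x) == pytest.approx(1.0)
        assert atat.spearman_concordance(x, x[::-1]) == pytest.approx(-1.0)

    def test_four_point_example(self):
        # d = (0, 1, -1, 0): rho = 1 - 6*2/(4*15) = 0.8
        rho = atat.spearman_concordance(
            np.array([1, 2, 3, 4]), np.array([1, 3, 2, 4])
        )
        assert rho == pytest.approx(0.8, abs=1e-12)

    def test_constant_input_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            atat.spearman_concordance(np.ones(5), np.arange(5.0))

    def test_too_short_rejected(self):
        with pytest.raises(InvalidArgumentError):
            atat.spearman_concordance(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
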