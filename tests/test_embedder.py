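"""Triplet sampling, the margin loss, and encoder training."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import atat
from atat.errors import ContractError, DegenerateInputError, InvalidArgumentError


class TestTripletLoss:
    @pytest.mark.parametrize("d_ap,d_an,alpha,expected", [
        (0.5, 0.2, 0.001, 0.301),
        (0.3, 0.3, 0.05, 0.05),       # equal distances -> the margin
        (0.0, 0.5, 0.001, 0.0),       # satisfied margin
        (0.0, 0.2, 0.2, 0.0),         # boundary: d_an - d_ap == alpha
        (1.0, 0.0, 0.5, 1.5),
    ])
    def test_closed_form(self, d_ap, d_an, alpha, expected):
        assert atat.triplet_loss(d_ap, d_an, alpha) == pytest.approx(
            expected, abs=1e-12
        )

    def test_negative_distance_rejected(self):
        with pytest.raises(InvalidArgumentError):
            atat.triplet_loss(-0.1, 0.2, 0.001)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        d_ap=st.floats(0, 10, allow_nan=False),
        d_an=st.floats(0, 10, allow_nan=False),
        alpha=st.floats(1e-6, 1, allow_nan=False),
    )
    def test_nonnegative_and_zero_iff_margin_met(self, d_ap, d_an, alpha):
        loss = atat.triplet_loss(d_ap, d_an, alpha)
        assert loss >= 0
        assert (loss == 0) == (d_an - d_ap >= alpha)


class TestSampleTriplets:
    def test_positives_adjacent_negatives_not(self):
        grid = atat.make_visium_grid(3, 3, 10)
        batch = atat.sample_triplets(grid, 100, seed=0)
        assert len(batch) == 100
        for a, p, n in zip(batch.anchors, batch.positives, batch.negatives):
            nb = grid.neighbors(a)
            assert p in nb
            assert n != a and n not in nb

    def test_deterministic_given_seed(self):
        grid = atat.make_visium_grid(4, 4, 10)
        b1 = atat.sample_triplets(grid, 50, seed=9)
        b2 = atat.sample_triplets(grid, 50, seed=9)
        assert (b1.anchors, b1.positives, b1.negatives) == \
            (b2.anchors, b2.positives, b2.negatives)

    def test_adjacent_pair_only_grid_is_degenerate(self):
        grid = atat.SpotGrid(
            spot_ids=["a", "b"],
            array_coords=[(0, 0), (0, 2)],
            pixel_coords=[(10.0, 10.0), (10.0, 20.0)],
            in_tissue=[True, True],
            spot_diameter_px=5,
        )
        with pytest.raises(DegenerateInputError):
            atat.sample_triplets(grid, 10, seed=0)

    def test_pooled_dataset_draws_negatives_across_slides(self):
        g = atat.make_visium_grid(3, 3, 10)
        tiles = atat.TileStack(
            tiles=np.zeros((9, 10, 10, 3), np.float32), spot_ids=list(g.spot_ids)
        )
        pooled_grid, _ = atat.pool_slides([(g, tiles), (g, tiles)])
        assert pooled_grid.n_spots == 18
        batch = atat.sample_triplets(pooled_grid, 300, seed=1)
        # positives stay on the anchor's slide; negatives cross slides
        slide_of = lambda s: s.split(":")[0]
        assert all(
            slide_of(a) == slide_of(p)
            for a, p in zip(batch.anchors, batch.positives)
        )
        assert any(
            slide_of(a) != slide_of(n)
            for a, n in zip(batch.anchors, batch.negatives)
        )


class TestTrainConfig:
    def test_published_full_scale_recipe(self):
        cfg = atat.TrainConfig.full_scale_defaults()
        assert cfg.margin == 0.001
        assert cfg.epochs == 1000
        assert cfg.batch_size == 768
        assert cfg.learning_rate == 0.05
        assert cfg.momentum == 0.9
        assert cfg.weight_decay == 1e-4
        assert cfg.encoder_size == "full"

    def test_invalid_margin_rejected(self):
        with pytest.raises(InvalidArgumentError):
            atat.TrainConfig(margin=0.0)


class TestTraining:
    def test_loss_decreases(self, trained):
        assert trained.encoder.loss_history[-1] < trained.encoder.loss_history[0]

    def test_identical_config_and_seed_reproduce_embeddings(self, slide3):
        grid = slide3.grid
        tiles = atat.extract_tiles(slide3.image, grid)
        tn = atat.normalize_tiles(tiles, atat.compute_tile_stats([tiles]))
        cfg = atat.TrainConfig(epochs=3, batch_size=64, seed=21)
        e1 = atat.embed_tiles(atat.train_encoder(tn, grid, cfg), tn)
        e2 = atat.embed_tiles(atat.train_encoder(tn, grid, cfg), tn)
        np.testing.assert_array_equal(e1.vectors, e2.vectors)

    def test_batch_larger_than_pool_rejected(self, trained):
        cfg = atat.TrainConfig(
            epochs=1, batch_size=64, triplets_per_epoch=32, seed=0
        )
        with pytest.raises(InvalidArgumentError):
            atat.train_encoder(trained.tiles, trained.grid, cfg)


class TestEmbedTiles:
    def test_embeddings_are_deterministic(self, trained):
        e1 = atat.embed_tiles(trained.encoder, trained.tiles)
        e2 = atat.embed_tiles(trained.encoder, trained.tiles)
        np.testing.assert_array_equal(e1.vectors, e2.vectors)
        assert np.all(np.isfinite(e1.vectors))
        assert e1.encoder_fingerprint == trained.encoder.fingerprint

    def test_statistics_mismatch_rejected(self, trained):
        rogue = atat.TileStack(
            tiles=trained.tiles.tiles,
            spot_ids=trained.tiles.spot_ids,
            channel_mean=trained.tiles.channel_mean + 1.0,
            channel_sd=trained.tiles.channel_sd,
            normalized=True,
        )
        with pytest.raises(ContractError):
            atat.embed_tiles(trained.encoder, rogue)

    def test_layers_separate_in_embedding_space(self, trained):
        from scipy.spatial.distance import pdist, squareform
        lab = trained.slide.truth_labels
        D = squareform(pdist(trained.emb.vectors))
        off_diag = ~np.eye(len(lab), dtype=bool)
        within = D[(lab[:, None] == lab[None, :]) & off_diag].mean()
        between = D[lab[:, None] != lab[None, :]].mean()
        assert between > within

    def test_checkpoint_round_trip(self, trained, tmp_path):
        path = tmp_path / "enc.npz"
        trained.encoder.save(path)
        again = atat.TileEncoder.load(path)
        assert again.fingerprint == trained.encoder.fingerprint
        e1 = atat.embed_tiles(trained.encoder, trained.tiles)
        e2 = atat.embed_tiles(again, trained.tiles)
        np.testing.assert_array_equal(e1.vectors, e2.vectors)
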