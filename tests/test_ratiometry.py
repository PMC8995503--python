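"""Tiling, masking, pixelwise ratios and the synthetic scene generator."""

import numpy as np
import pytest

import _oracles
from attenkit.ratiometry import (
    ChannelImagePair,
    SyntheticScene,
    aggregate_replicates,
    generate_synthetic_pair,
    percent_of_control,
    pixel_mask,
    pixelwise_ratio,
    read_pair,
    subdivide_tiles,
    suggested_thresholds,
    write_pair,
)


def flat_pair(green, red):
    return ChannelImagePair(green=np.asarray(green), red=np.asarray(red))


SMALL_SCENE = dict(shape=(256, 256), n_cells=14)


class TestSubdivideTiles:
    def test_exact_division_yields_equal_tiles(self):
        pair = flat_pair(np.ones((100, 100)), np.ones((100, 100)))
        tiles = subdivide_tiles(pair, 10)
        assert len(tiles) == 100
        assert all(t.shape == (10, 10) for t in tiles)

    def test_948_composite_on_10x10_grid_discards_remainder(self):
        pair = flat_pair(np.ones((948, 948)), np.ones((948, 948)))
        tiles = subdivide_tiles(pair, 10)
        assert len(tiles) == 100
        assert all(t.shape == (94, 94) for t in tiles)

    def test_grid_of_one_is_identity(self):
        img = np.arange(25.0).reshape(5, 5)
        tiles = subdivide_tiles(flat_pair(img, img), 1)
        assert len(tiles) == 1
        np.testing.assert_array_equal(tiles[0].green, img)

    def test_tiling_is_lossless_modulo_remainder_crop(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 100, (37, 37))
        pair = flat_pair(img, img)
        tiles = subdivide_tiles(pair, 5)
        rebuilt = np.block(
            [[tiles[r * 5 + c].green for c in range(5)] for r in range(5)]
        )
        np.testing.assert_array_equal(rebuilt, img[:35, :35])

    def test_sub_pixel_tiles_rejected(self):
        pair = flat_pair(np.ones((3, 3)), np.ones((3, 3)))
        with pytest.raises(ValueError):
            subdivide_tiles(pair, 4)


class TestPixelMask:
    def test_all_zero_images_give_empty_mask(self):
        pair = flat_pair(np.zeros((8, 8)), np.zeros((8, 8)))
        assert pixel_mask(pair, 0.0, 0.0).sum() == 0

    def test_zero_thresholds_on_positive_images_give_full_mask(self):
        pair = flat_pair(np.ones((8, 8)), np.ones((8, 8)))
        assert pixel_mask(pair, 0.0, 0.0).all()

    def test_red_only_mode_ignores_green_channel(self):
        green = np.zeros((4, 4))
        red = np.full((4, 4), 10.0)
        pair = flat_pair(green, red)
        assert not pixel_mask(pair, 5.0, 5.0).any()
        assert pixel_mask(pair, 5.0, 5.0, red_only=True).all()

    def test_recall_of_painted_cells_at_three_sigma_threshold(self):
        scene = SyntheticScene(seed=5, true_fraction=0.35, **SMALL_SCENE)
        pair, truth = generate_synthetic_pair(scene)
        tr, tg = suggested_thresholds(scene)
        mask = pixel_mask(pair, tr, tg)
        # recall over the painted foreground
        fg = truth["foreground_pixels"]
        scene0 = SyntheticScene(seed=5, true_fraction=0.35,
                                background_noise_sd=0.0, background_mean=0.0,
                                **SMALL_SCENE)
        pair0, _ = generate_synthetic_pair(scene0)
        painted = pair0.red > 0
        recall = (mask & painted).sum() / fg
        assert recall >= 0.99


class TestPixelwiseRatio:
    def test_equal_channels_give_unit_ratio(self):
        img = np.full((6, 6), 50.0)
        pair = flat_pair(img, img)
        m = pixelwise_ratio(pair, np.ones((6, 6), dtype=bool))
        assert m.mean_ratio == pytest.approx(1.0)
        assert m.pixel_count == 36

    def test_half_intensity_green_gives_half_ratio(self):
        red = np.full((6, 6), 50.0)
        pair = flat_pair(0.5 * red, red)
        m = pixelwise_ratio(pair, np.ones((6, 6), dtype=bool))
        assert m.mean_ratio == pytest.approx(0.5)

    def test_empty_mask_is_a_no_signal_result_not_an_error(self):
        pair = flat_pair(np.ones((4, 4)), np.ones((4, 4)))
        m = pixelwise_ratio(pair, np.zeros((4, 4), dtype=bool))
        assert m.pixel_count == 0 and m.mean_ratio is None

    def test_matches_naive_double_loop_exactly(self):
        rng = np.random.default_rng(3)
        green = rng.uniform(1, 500, (17, 23))
        red = rng.uniform(1, 500, (17, 23))
        mask = rng.uniform(0, 1, (17, 23)) > 0.4
        pair = flat_pair(green, red)
        ours = pixelwise_ratio(pair, mask)
        want, n = _oracles.naive_masked_mean_ratio(
            green.tolist(), red.tolist(), mask.tolist()
        )
        assert ours.pixel_count == n
        assert ours.mean_ratio == pytest.approx(want, rel=1e-12)

    def test_invariant_under_common_rescaling(self):
        rng = np.random.default_rng(4)
        green = rng.uniform(1, 500, (12, 12))
        red = rng.uniform(1, 500, (12, 12))
        mask = np.ones((12, 12), dtype=bool)
        a = pixelwise_ratio(flat_pair(green, red), mask)
        b = pixelwise_ratio(flat_pair(3.7 * green, 3.7 * red), mask)
        assert a.mean_ratio == pytest.approx(b.mean_ratio)

    def test_ratio_of_sums_estimator_differs_but_agrees_on_constant_ratio(self):
        red = np.full((5, 5), 40.0)
        pair = flat_pair(0.25 * red, red)
        mask = np.ones((5, 5), dtype=bool)
        a = pixelwise_ratio(pair, mask, estimator="mean_of_ratios")
        b = pixelwise_ratio(pair, mask, estimator="ratio_of_sums")
        assert a.mean_ratio == pytest.approx(b.mean_ratio) == pytest.approx(0.25)


class TestPercentOfControl:
    def test_sample_equal_to_control_is_100(self):
        img = np.full((5, 5), 20.0)
        mask = np.ones((5, 5), dtype=bool)
        m = pixelwise_ratio(flat_pair(img, img), mask)
        assert percent_of_control(m, m) == pytest.approx(100.0)

    def test_half_ratio_is_50(self):
        red = np.full((5, 5), 20.0)
        mask = np.ones((5, 5), dtype=bool)
        s = pixelwise_ratio(flat_pair(0.5 * red, red), mask)
        c = pixelwise_ratio(flat_pair(red, red), mask)
        assert percent_of_control(s, c) == pytest.approx(50.0)

    def test_synthetic_scene_at_35_percent_recovered_within_two_points(self):
        scene = SyntheticScene(seed=11, true_fraction=0.35, **SMALL_SCENE)
        control = SyntheticScene(seed=12, true_fraction=1.0, **SMALL_SCENE)
        ps, truth = generate_synthetic_pair(scene)
        pc, _ = generate_synthetic_pair(control)
        assert truth["foreground_pixels"] >= 1000
        tr, tg = suggested_thresholds(scene)
        ms = pixelwise_ratio(ps, pixel_mask(ps, tr, tg))
        mc = pixelwise_ratio(pc, pixel_mask(pc, tr, tg))
        assert percent_of_control(ms, mc) == pytest.approx(35.0, abs=2.0)

    def test_undefined_control_rejected(self):
        pair = flat_pair(np.ones((4, 4)), np.ones((4, 4)))
        empty = pixelwise_ratio(pair, np.zeros((4, 4), dtype=bool))
        full = pixelwise_ratio(pair, np.ones((4, 4), dtype=bool))
        with pytest.raises(ValueError):
            percent_of_control(full, empty)


class TestAggregateReplicates:
    def test_single_tile_single_replicate_passes_through(self):
        pair = flat_pair(np.full((5, 5), 10.0), np.full((5, 5), 20.0))
        m = pixelwise_ratio(pair, np.ones((5, 5), dtype=bool))
        out = aggregate_replicates({"cond": [[m]]})["cond"]
        assert out["mean_ratio"] == pytest.approx(0.5)
        assert out["n_replicates"] == 1 and out["sem"] is None

    def test_two_identical_replicates_have_zero_sem(self):
        pair = flat_pair(np.full((5, 5), 10.0), np.full((5, 5), 20.0))
        m = pixelwise_ratio(pair, np.ones((5, 5), dtype=bool))
        out = aggregate_replicates({"cond": [[m], [m]]})["cond"]
        assert out["sem"] == 0.0 and out["ci95_halfwidth"] == 0.0

    def test_tiles_are_pixel_weighted_within_a_replicate(self):
        big = flat_pair(np.full((4, 4), 10.0), np.full((4, 4), 10.0))  # ratio 1
        small = flat_pair(np.full((2, 2), 10.0), np.full((2, 2), 20.0))  # ratio .5
        m_big = pixelwise_ratio(big, np.ones((4, 4), dtype=bool))
        m_small = pixelwise_ratio(small, np.ones((2, 2), dtype=bool))
        out = aggregate_replicates({"c": [[m_big, m_small]]})["c"]
        assert out["mean_ratio"] == pytest.approx((16 * 1.0 + 4 * 0.5) / 20)

    def test_recovers_inter_replicate_sem_on_simulated_data(self):
        rng = np.random.default_rng(8)
        errs = []
        for _ in range(300):
            true_sd = 0.05
            reps = []
            for _ in range(3):
                r = max(1e-3, rng.normal(0.5, true_sd))
                pair = flat_pair(np.full((4, 4), 10.0 * r), np.full((4, 4), 10.0))
                reps.append([pixelwise_ratio(pair, np.ones((4, 4), dtype=bool))])
            out = aggregate_replicates({"c": reps})["c"]
            errs.append(out["sem"])
        # E[SEM] for n=3 normal samples: sd/sqrt(3) * c4 correction ~ 0.0256
        assert np.mean(errs) == pytest.approx(0.05 / np.sqrt(3), rel=0.15)


class TestSyntheticGenerator:
    def test_zero_cells_yields_background_only(self):
        scene = SyntheticScene(n_cells=0, shape=(64, 64), seed=1)
        pair, truth = generate_synthetic_pair(scene)
        assert truth["foreground_pixels"] == 0
        assert pair.red.mean() == pytest.approx(scene.background_mean, abs=5.0)

    def test_unit_fraction_zero_noise_green_equals_red_on_cells(self):
        scene = SyntheticScene(
            n_cells=6, shape=(128, 128), seed=2, true_fraction=1.0,
            multiplicative_noise_sd=0.0, background_noise_sd=0.0,
            background_mean=0.0,
        )
        pair, _ = generate_synthetic_pair(scene)
        np.testing.assert_array_equal(pair.green, pair.red)

    def test_identical_seed_gives_bit_identical_tiffs(self, tmp_path):
        for run in ("a", "b"):
            scene = SyntheticScene(seed=9, **SMALL_SCENE)
            pair, truth = generate_synthetic_pair(scene)
            write_pair(
                pair,
                tmp_path / f"{run}_g.tif",
                tmp_path / f"{run}_r.tif",
                truth,
                tmp_path / f"{run}.json",
            )
        assert (tmp_path / "a_g.tif").read_bytes() == (tmp_path / "b_g.tif").read_bytes()
        assert (tmp_path / "a_r.tif").read_bytes() == (tmp_path / "b_r.tif").read_bytes()

    def test_tiff_roundtrip_preserves_intensities(self, tmp_path):
        scene = SyntheticScene(seed=3, shape=(64, 64), n_cells=3, cell_radius=(4, 8))
        pair, _ = generate_synthetic_pair(scene)
        write_pair(pair, tmp_path / "g.tif", tmp_path / "r.tif")
        back = read_pair(tmp_path / "g.tif", tmp_path / "r.tif")
        np.testing.assert_array_equal(back.green, pair.green)
        np.testing.assert_array_equal(back.red, pair.red)

    def test_infeasible_packing_raises(self):
        with pytest.raises(RuntimeError):
            generate_synthetic_pair(SyntheticScene(n_cells=200, shape=(96, 96), seed=0))

    def test_mismatched_channel_shapes_rejected(self):
        with pytest.raises(ValueError):
            ChannelImagePair(green=np.ones((4, 4)), red=np.ones((4, 5)))
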