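import numpy as np
import pytest

from gliocascade.errors import ConfigError, DataError, ShapeError
from gliocascade.io_volumes import region_mask
from gliocascade.segmenter import (SegmenterConfig, TrainConfig, UNetSegmenter,
                                   build_segmenter, forward, predict_mask)

FILTER_LADDERS = {2: (8, 16), 3: (8, 16, 32), 4: (8, 16, 32, 64)}


def unet_param_count_oracle(depth, filters, in_channels=4, mode="nearest"):
    """Independent layer-by-layer weight-shape summation (k^3*c_in*c_out
    + c_out per convolution)."""
    total = 0
    c = in_channels
    for f in filters:
        total += 27 * c * f + f          # conv1
        total += 27 * f * f + f          # conv2
        c = f
    for f in reversed(filters):
        if mode == "nearest":
            total += 27 * c * f + f      # conv after upsampling
        else:
            total += 8 * c * f + f       # 2x2x2 transposed conv
        total += 27 * (2 * f) * f + f    # post-concat conv
        total += 27 * f * f + f
        c = f
    total += 1 * c * 1 + 1               # 1x1x1 head
    return total


class TestArchitecture:
    def test_depth4_encoder_shrinks_32_to_2(self):
        est = build_segmenter(input_extent=32)
        stages = est.model_.describe(32)
        extents = [s["extent_out"] for s in stages if s["stage"].startswith("enc")]
        assert extents == [16, 8, 4, 2]
        assert [s for s in stages if s["stage"] == "bottleneck"][0]["extent_in"] == 2

    def test_depth2_encoder_shrinks_32_to_8(self):
        est = build_segmenter(SegmenterConfig(depth=2, encoder_filters=(8, 16)),
                              input_extent=32)
        stages = est.model_.describe(32)
        assert stages[1]["extent_out"] == 8

    def test_feature_maps_grow_4_to_64(self):
        est = build_segmenter(input_extent=32)
        stages = est.model_.describe(32)
        assert stages[0]["channels_in"] == 4
        assert [s for s in stages if s["stage"] == "bottleneck"][0]["channels_out"] == 64

    def test_decoder_restores_input_extent(self):
        est = build_segmenter(input_extent=32)
        stages = est.model_.describe(32)
        assert stages[-1]["extent_out"] == 32

    def test_skip_concatenation_doubles_channels(self):
        est = build_segmenter(input_extent=32)
        for s in est.model_.describe(32):
            if s["stage"].startswith("dec"):
                assert s["channels_after_concat"] == 2 * s["channels_after_up"]

    @pytest.mark.parametrize("depth", [2, 3, 4])
    @pytest.mark.parametrize("mode", ["nearest", "transposed"])
    def test_parameter_count_matches_closed_form(self, depth, mode):
        filters = FILTER_LADDERS[depth]
        est = build_segmenter(
            SegmenterConfig(depth=depth, encoder_filters=filters, upsample_mode=mode),
            input_extent=32)
        assert est.n_parameters_ == unet_param_count_oracle(depth, filters, mode=mode)

    def test_indivisible_extent_rejected(self):
        with pytest.raises(ConfigError):
            build_segmenter(input_extent=24)  # 24 not divisible by 2^4

    def test_bad_filter_ladder_rejected(self):
        with pytest.raises(ConfigError):
            SegmenterConfig(depth=4, encoder_filters=(8, 16))


class TestForward:
    def test_outputs_are_probabilities(self, tiny_preprocessed, rng):
        est = UNetSegmenter(depth=2, encoder_filters=(4, 8), random_state=0).build(16)
        x = rng.normal(size=(3, 4, 16, 16, 16)).astype(np.float32)
        p = est.predict_proba(x)
        assert p.shape == (3, 16, 16, 16)
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_inference_is_deterministic(self, rng):
        est = UNetSegmenter(depth=2, encoder_filters=(4, 8), random_state=0).build(16)
        x = rng.normal(size=(1, 4, 16, 16, 16)).astype(np.float32)
        np.testing.assert_array_equal(est.predict_proba(x), est.predict_proba(x))

    def test_batch_forward_equals_per_sample_forward(self, rng):
        est = UNetSegmenter(depth=2, encoder_filters=(4, 8), random_state=0).build(16)
        x = rng.normal(size=(3, 4, 16, 16, 16)).astype(np.float32)
        batch = est.predict_proba(x)
        singles = np.stack([est.predict_proba(x[i:i + 1])[0] for i in range(3)])
        np.testing.assert_allclose(batch, singles, atol=1e-6)

    def test_shape_mismatch_rejected(self, rng):
        est = UNetSegmenter(depth=2, encoder_filters=(4, 8), random_state=0).build(16)
        with pytest.raises(ShapeError):
            est.predict_proba(rng.normal(size=(1, 3, 16, 16, 16)))


class TestThresholding:
    def test_uniform_probability_thresholds_to_all_ones(self):
        # logic check on predict: p=0.7 everywhere, threshold 0.5
        est = UNetSegmenter(depth=2, encoder_filters=(4, 8), random_state=0).build(16)
        p = np.full((16, 16, 16), 0.7)
        assert np.all((p >= est.threshold))

    def test_threshold_bounds_enforced(self, rng):
        est = UNetSegmenter(depth=2, encoder_filters=(4, 8), random_state=0).build(16)
        x = rng.normal(size=(1, 4, 16, 16, 16)).astype(np.float32)
        with pytest.raises(ConfigError):
            est.predict(x, threshold=1.0)

    def test_mask_size_non_increasing_in_threshold(self, rng):
        est = UNetSegmenter(depth=2, encoder_filters=(4, 8), random_state=0).build(16)
        x = rng.normal(size=(1, 4, 16, 16, 16)).astype(np.float32)
        sizes = [est.predict(x, threshold=t).sum() for t in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert sizes == sorted(sizes, reverse=True)


class TestTraining:
    def test_single_phantom_overfit(self, hgg_preprocessed):
        tensor, labels = hgg_preprocessed
        y = region_mask(labels, "complete").mask
        est = UNetSegmenter(epochs=80, batch_size=1, random_state=0)
        est.fit(tensor[None], y[None])
        assert len(est.history_) == 80
        assert est.history_["dice"].iloc[-1] >= 0.95

    def test_all_background_targets_learn_empty_masks(self, rng):
        x = rng.normal(size=(4, 4, 16, 16, 16)).astype(np.float32)
        y = np.zeros((4, 16, 16, 16), dtype=np.uint8)
        est = UNetSegmenter(depth=2, encoder_filters=(4, 8), epochs=20,
                            batch_size=4, random_state=0)
        est.fit(x, y)
        frac = est.predict(x).mean()
        assert frac < 0.01

    def test_training_is_reproducible(self, tiny_preprocessed):
        tensor, labels = tiny_preprocessed
        y = region_mask(labels, "complete").mask
        runs = []
        for _ in range(2):
            est = UNetSegmenter(depth=2, encoder_filters=(4, 8), epochs=3,
                                batch_size=1, random_state=5)
            est.fit(tensor[None], y[None])
            runs.append((est.history_.copy(), est.predict_proba(tensor[None])))
        assert runs[0][0].equals(runs[1][0])
        np.testing.assert_array_equal(runs[0][1], runs[1][1])

    def test_empty_training_set_rejected(self):
        est = UNetSegmenter()
        with pytest.raises(DataError):
            est.fit(np.zeros((0, 4, 16, 16, 16)), np.zeros((0, 16, 16, 16)))

    def test_zero_epochs_rejected(self):
        with pytest.raises(ConfigError):
            TrainConfig(epochs=0)

    def test_soft_dice_loss_trains(self, tiny_preprocessed):
        tensor, labels = tiny_preprocessed
        y = region_mask(labels, "complete").mask
        est = UNetSegmenter(depth=2, encoder_filters=(4, 8), epochs=15, batch_size=1,
                            loss="soft_dice", random_state=0)
        est.fit(tensor[None], y[None])
        assert est.history_["loss"].iloc[-1] < est.history_["loss"].iloc[0]


class TestPersistence:
    def test_checkpoint_round_trip(self, tmp_path, rng):
        est = UNetSegmenter(depth=2, encoder_filters=(4, 8), random_state=0).build(16)
        x = rng.normal(size=(1, 4, 16, 16, 16)).astype(np.float32)
        before = est.predict_proba(x)
        est.save(tmp_path / "seg.npz")
        back = UNetSegmenter.load(tmp_path / "seg.npz")
        np.testing.assert_array_equal(back.predict_proba(x), before)


class TestFunctionalWrappers:
    def test_forward_and_predict_mask(self, rng):
        est = UNetSegmenter(depth=2, encoder_filters=(4, 8), random_state=0).build(16)
        x = rng.normal(size=(4, 16, 16, 16)).astype(np.float32)
        p = forward(est, x)
        assert p.shape == (1, 16, 16, 16)
        mask = predict_mask(est, x)
        assert mask.region == "complete"
        np.testing.assert_array_equal(mask.mask, (p[0] >= 0.5).astype(np.uint8))
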