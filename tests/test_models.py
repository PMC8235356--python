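"""Feature extractors, parameter counting, GAP features, pretraining
and fine-tuning contracts."""

import numpy as np
import pytest

from ventasync import models as md
from ventasync.nn import (Conv2D, Dense, GlobalAvgPool, PlateauScheduler,
                          Sequential, TrainingConfig)

TINY_LAYER_TABLE = [
    # (kind, params) hand-computed from the documented layer table:
    ("conv 5x5x3->16", 5 * 5 * 3 * 16),
    ("bn 16", 4 * 16),
    ("conv 3x3x16->32", 3 * 3 * 16 * 32),
    ("bn 32", 4 * 32),
    ("conv 3x3x32->64", 3 * 3 * 32 * 64),
    ("bn 64", 4 * 64),
    ("dense 64->2", 64 * 2 + 2),
]


class TestParameterCounts:
    def test_mobilenet_matches_published_total(self):
        model = md.build_model(md.FeatureExtractorSpec("mobilenet_v1"))
        assert md.count_parameters(model) == 3_230_914

    def test_inception_resnet_v2_matches_published_total(self):
        model = md.build_model(md.FeatureExtractorSpec("inception_resnet_v2"))
        assert md.count_parameters(model) == 54_339_810

    def test_vgg16_bn_matches_published_total(self):
        # 13 VGG16 convs + 5 per-block batch norms + 512->2 head
        model = md.build_model(md.FeatureExtractorSpec("vgg16_bn"))
        assert md.count_parameters(model) == 14_721_602

    def test_tiny_cnn_matches_layer_table_oracle(self):
        model = md.build_model(md.FeatureExtractorSpec("tiny_cnn"))
        expect = sum(n for _, n in TINY_LAYER_TABLE)
        assert md.count_parameters(model) == expect

    def test_headless_dense_count(self):
        net = Sequential([Dense(1024, 2)])
        assert net.n_params() == 2050

    def test_count_equals_tensor_enumeration_oracle(self):
        model = md.build_model(md.FeatureExtractorSpec("mobilenet_v1"))
        brute = sum(a.size for _, _, a in
                    model.extractor.param_tensors(trainable_only=False))
        brute += sum(a.size for a in model.head.params.values())
        assert md.count_parameters(model) == brute

    def test_unknown_architecture_rejected(self):
        with pytest.raises(ValueError):
            md.FeatureExtractorSpec("resnet50")


class TestFeatures:
    def test_feature_dims(self, small_images):
        batch = small_images[:2]
        for name, dim in (("tiny_cnn", 64), ("mobilenet_v1", 1024)):
            model = md.build_model(md.FeatureExtractorSpec(name))
            feats = md.extract_features(model, batch)
            assert feats.shape == (2, dim)

    def test_inception_feature_dim(self, small_images):
        model = md.build_model(md.FeatureExtractorSpec("inception_resnet_v2"))
        feats = md.extract_features(model, small_images[:1])
        assert feats.shape == (1, 1536)

    def test_gap_is_spatial_mean_closed_form(self):
        # constant input through one conv layer: GAP equals the full kernel
        # sum times the constant (interior), computable by hand
        rng = np.random.default_rng(0)
        conv = Conv2D(1, 3, 1, rng=rng)  # 1x1 kernel: exactly c * w everywhere
        net = Sequential([conv, GlobalAvgPool()])
        c = 0.7
        x = np.full((1, 8, 8, 1), c, np.float32)
        out = net.forward(x)
        np.testing.assert_allclose(out[0], c * conv.w[0, 0, 0, :], rtol=1e-6)

    def test_gap_invariant_to_spatial_shuffle(self, rng):
        maps = rng.random((1, 7, 7, 16)).astype(np.float32)
        gap = GlobalAvgPool()
        a = gap.forward(maps)
        sh = maps.reshape(1, 49, 16)[:, rng.permutation(49), :].reshape(maps.shape)
        np.testing.assert_allclose(a, gap.forward(sh), rtol=1e-6)

    def test_features_deterministic(self, small_images):
        model = md.build_model(md.FeatureExtractorSpec("tiny_cnn"), seed=3)
        f1 = md.extract_features(model, small_images[:4])
        f2 = md.extract_features(model, small_images[:4])
        np.testing.assert_array_equal(f1, f2)


class TestPlateauScheduler:
    def test_lr_reduced_exactly_at_plateau_plus_patience(self):
        sched = PlateauScheduler(initial_lr=1e-3, patience=10, factor=0.1)
        losses = [1.0, 0.9, 0.8] + [0.85] * 30  # plateau starts after epoch 3
        for loss in losses:
            if not sched.step(loss):
                break
        reduce_events = [e for e in sched.events if e[0] == "reduce_lr"]
        assert reduce_events[0][1] == 3 + 10
        assert reduce_events[0][2] == pytest.approx(1e-4)

    def test_training_stops_on_continued_stagnation(self):
        sched = PlateauScheduler(patience=5, stop_after_reductions=2)
        sched.step(1.0)
        alive = [sched.step(1.5) for _ in range(20)]
        assert not alive[-1]
        stop = [e for e in sched.events if e[0] == "stop"]
        assert stop[0][1] == 1 + 15  # two reductions then the stop check

    def test_improvement_resets_counters(self):
        sched = PlateauScheduler(patience=3)
        for loss in [1.0, 1.1, 1.1, 0.9, 1.0, 1.0]:
            assert sched.step(loss)
        assert sched.events == []
        assert sched.best == pytest.approx(0.9)


@pytest.fixture(scope="module")
def pretrained():
    cfg = TrainingConfig(max_epochs=4, patience_epochs=2,
                         stop_after_reductions=1, seed=1)
    return md.pretrain_source_task(md.FeatureExtractorSpec("tiny_cnn"),
                                   cfg, n_per_class=12)


class TestPretrainAndFineTune:
    def test_source_task_beats_chance(self, pretrained):
        _, hist = pretrained
        x, y = md.make_source_dataset(8, seed=99)
        extractor = pretrained[0]
        net = Sequential([extractor, GlobalAvgPool()])
        feats = net.forward(x.astype(np.float32))
        # linear probe on held-out source images
        head, _ = md.fit_dense_probe(feats, y, n_classes=5)
        acc = (np.argmax(head.forward(feats.astype(np.float32)), 1) == y).mean()
        assert acc > 1 / 5

    def test_pretraining_moves_weights(self, pretrained):
        extractor, _ = pretrained
        fresh = md.build_extractor_raw("tiny_cnn", 1)
        dist = sum(float(np.sum((a - b) ** 2)) for (_, _, a), (_, _, b) in
                   zip(extractor.param_tensors(), fresh.param_tensors()))
        assert dist > 0

    def test_frozen_fine_tune_keeps_extractor_bits(self, small_images):
        model = md.build_model(md.FeatureExtractorSpec("tiny_cnn"), seed=3)
        before = [a.copy() for _, _, a in
                  model.extractor.param_tensors(trainable_only=False)]
        y = np.array([1 if im.label == "DT" else 0 for im in small_images])
        cfg = TrainingConfig(max_epochs=5, patience_epochs=2,
                             stop_after_reductions=1, seed=3)
        md.fine_tune(model, small_images, y, cfg, freeze_extractor=True)
        after = [a for _, _, a in
                 model.extractor.param_tensors(trainable_only=False)]
        for b, a in zip(before, after):
            np.testing.assert_array_equal(b, a)

    def test_unfrozen_fine_tune_descends(self, small_images):
        model = md.build_model(md.FeatureExtractorSpec("tiny_cnn"), seed=3)
        y = np.array([1 if im.label == "DT" else 0 for im in small_images])
        cfg = TrainingConfig(max_epochs=6, patience_epochs=3,
                             stop_after_reductions=1, seed=3, batch_size=16)
        hist = md.fine_tune(model, small_images, y, cfg,
                            freeze_extractor=False)
        assert hist["train_loss"][-1] < hist["train_loss"][0]

    def test_single_class_rejected(self, small_images):
        model = md.build_model(md.FeatureExtractorSpec("tiny_cnn"))
        with pytest.raises(ValueError, match="both classes"):
            md.fine_tune(model, small_images[:4], np.zeros(4, int))
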