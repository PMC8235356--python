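"""Class activation maps: oracle agreement, linearity, rendering."""

import numpy as np
import pytest
from PIL import Image

from ventasync import interpret, models as md
from ventasync.preprocess import FusedImage


@pytest.fixture(scope="module")
def toy_model():
    """tiny_cnn model with float64 weights for exact oracle comparison."""
    model = md.build_model(md.FeatureExtractorSpec("tiny_cnn"), seed=6)
    for layer, name, arr in model.extractor.param_tensors(trainable_only=False):
        setattr(layer, name, arr.astype(np.float64))
    model.head.w = model.head.w.astype(np.float64)
    model.head.b = model.head.b.astype(np.float64)
    return model


@pytest.fixture(scope="module")
def toy_image():
    rng = np.random.default_rng(6)
    return rng.random((224, 224, 3))


class TestComputeCam:
    def test_matches_triple_loop_oracle(self, toy_model, toy_image):
        cam = interpret.compute_cam(toy_model, toy_image, 1)
        maps = md.feature_maps(toy_model, toy_image)[0]
        w = toy_model.head.w
        expect = np.zeros(maps.shape[:2])
        for u in range(maps.shape[2]):
            for x in range(maps.shape[0]):
                for y in range(maps.shape[1]):
                    expect[x, y] += w[u, 1] * maps[x, y, u]
        assert np.abs(cam.raw - expect).max() < 1e-10

    def test_constant_maps_give_uniform_cam(self, toy_model):
        # linearity: constant feature maps c -> raw map uniformly sum(w_u*c)
        c = 0.3
        maps = np.full((1, 14, 14, 64), c)
        w = toy_model.head.w
        raw = maps[0] @ w[:, 0]
        assert np.allclose(raw, c * w[:, 0].sum())

    def test_class_maps_differ_when_weights_differ(self, toy_model, toy_image):
        cam0 = interpret.compute_cam(toy_model, toy_image, 0)
        cam1 = interpret.compute_cam(toy_model, toy_image, 1)
        assert not np.allclose(cam0.raw, cam1.raw)

    def test_linearity_in_head_weights(self, toy_model, toy_image):
        w_orig = toy_model.head.w.copy()
        cam_a = interpret.compute_cam(toy_model, toy_image, 0).raw
        toy_model.head.w = np.roll(w_orig, 1, axis=0)
        cam_b = interpret.compute_cam(toy_model, toy_image, 0).raw
        toy_model.head.w = w_orig + np.roll(w_orig, 1, axis=0)
        cam_sum = interpret.compute_cam(toy_model, toy_image, 0).raw
        toy_model.head.w = w_orig
        assert np.abs(cam_sum - (cam_a + cam_b)).max() < 1e-10

    def test_upsampled_normalized_and_argmax_preserved(self, toy_model,
                                                       toy_image):
        cam = interpret.compute_cam(toy_model, toy_image, 1)
        assert cam.upsampled.shape == (224, 224)
        assert cam.upsampled.min() == 0 and cam.upsampled.max() == 1
        rx, ry = np.unravel_index(cam.raw.argmax(), cam.raw.shape)
        ux, uy = np.unravel_index(cam.upsampled.argmax(),
                                  cam.upsampled.shape)
        scale = 224 / cam.raw.shape[0]
        assert abs(ux - rx * scale) <= scale
        assert abs(uy - ry * scale) <= scale

    def test_svm_head_rejected(self, toy_model, toy_image):
        class FakeSVM:
            pass
        model = md.PVAModel(spec=toy_model.spec, extractor=toy_model.extractor,
                            gap=toy_model.gap, head=FakeSVM())
        with pytest.raises(ValueError, match="dense"):
            interpret.compute_cam(model, toy_image, 0)


class TestCamLocalization:
    def test_evidence_concentrates_on_expiratory_notch(self):
        """End-to-end trained models place above-uniform top-decile CAM
        mass on the ineffective-effort notch columns in most seeds."""
        from ventasync import evaluate as ev, synth
        from ventasync.nn import TrainingConfig

        wins = 0
        seeds = range(5)
        for seed in seeds:
            rec = synth.generate_dataset({"IEE": 40, "OTHER": 40},
                                         noise_sd=0.0, seed=seed)
            data = ev.binary_task_arrays(rec, "IEE")
            model = md.build_model(md.FeatureExtractorSpec("tiny_cnn"),
                                   seed=seed)
            cfg = TrainingConfig(max_epochs=15, patience_epochs=5,
                                 stop_after_reductions=1, seed=seed,
                                 batch_size=16)
            md.fine_tune(model, data["images"], data["y"], cfg,
                         freeze_extractor=False)
            pred = model.predict(data["images"])
            ratios = []
            for j in np.nonzero((data["y"] == 1) & (pred == 1))[0][:10]:
                cyc = rec.cycles[data["ids"][j]]
                lo, hi = _notch_columns(cyc)
                cam = interpret.compute_cam(model, data["images"][j], 1)
                frac = interpret.top_decile_mass_in_columns(cam, (lo, hi))
                ratios.append(frac / ((hi - lo) / 224))
            wins += bool(ratios) and np.median(ratios) > 1
        assert wins > len(seeds) / 2


def _notch_columns(cyc):
    """Image columns spanned by the above-envelope expiratory excursion."""
    flow = cyc.flow
    e0 = int(np.argmin(flow))
    seg = flow[e0:]
    idx = np.arange(10, 25)
    coef = np.polyfit(idx, np.log(np.clip(-seg[idx], 1e-9, None)), 1)
    env = -np.exp(coef[1] + coef[0] * np.arange(len(seg)))
    cols = np.nonzero((seg - env) > 0.05)[0] + e0
    lo = int(cols.min() / len(flow) * 224)
    hi = int(cols.max() / len(flow) * 224) + 1
    return lo, hi


class TestRenderOverlay:
    def test_png_decodes_to_rgb_224(self, toy_model, toy_image, tmp_path):
        cam = interpret.compute_cam(toy_model, toy_image, 1)
        out = tmp_path / "overlay.png"
        interpret.render_overlay(cam, FusedImage(pixels=toy_image), out)
        with Image.open(out) as im:
            assert im.size == (224, 224)
            assert im.mode in ("RGB", "RGBA")

    def test_alpha_zero_reproduces_input(self, toy_model, toy_image, tmp_path):
        cam = interpret.compute_cam(toy_model, toy_image, 1)
        out = tmp_path / "identity.png"
        interpret.render_overlay(cam, FusedImage(pixels=toy_image), out,
                                 alpha=0.0)
        with Image.open(out) as im:
            arr = np.asarray(im)[:, :, :3]
        expect = np.clip(toy_image * 255, 0, 255).astype(np.uint8)
        np.testing.assert_array_equal(arr, expect)

    def test_unwritable_path_raises(self, toy_model, toy_image):
        cam = interpret.compute_cam(toy_model, toy_image, 1)
        with pytest.raises(OSError):
            interpret.render_overlay(cam, FusedImage(pixels=toy_image),
                                     "/nonexistent-dir/x.png")
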