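"""GAP-headed classification models and the transfer-learning workflow.

A PVA model is a convolutional trunk, a global average pooling (GAP)
layer, and a two-unit dense softmax head (one target asynchrony class
versus OTHER).  The trunk can be initialized randomly or from weights
pretrained on a source task.  Because the original large-scale source
corpus is external, pretraining here uses a procedurally generated
curve-shape image task rendered through the same plotting pipeline as
the breath images; an optional hook accepts externally obtained weights
for the published architectures.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np

from . import archs
from .nn.layers import Dense, GlobalAvgPool
from .nn.network import Sequential
from .nn.train import TrainingConfig, fit
from .preprocess import IMG_SIZE, minmax_normalize, rasterize, fuse_channels

INIT_MODES = ("random", "source_pretrained", "external_pretrained")


@dataclass(frozen=True)
class FeatureExtractorSpec:
    """Which trunk to build and how to initialize it."""

    name: str = "tiny_cnn"
    init: str = "random"
    input_size: tuple = (IMG_SIZE, IMG_SIZE, 3)

    def __post_init__(self):
        if self.name not in archs.FEATURE_DIMS:
            raise ValueError(f"unknown extractor {self.name!r}")
        if self.init not in INIT_MODES:
            raise ValueError(f"unknown init mode {self.init!r}")

    @property
    def feature_dim(self) -> int:
        return archs.FEATURE_DIMS[self.name]


@dataclass
class PVAModel:
    """Trunk + GAP + dense softmax head."""

    spec: FeatureExtractorSpec
    extractor: Sequential
    gap: GlobalAvgPool
    head: Dense
    n_params: int = 0

    @property
    def feature_dim(self) -> int:
        return self.spec.feature_dim

    def full_network(self) -> Sequential:
        return Sequential([self.extractor, self.gap, self.head],
                          name=self.spec.name + "_full")

    def predict_logits(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        feats = extract_features(self, x, batch_size=batch_size)
        return self.head.forward(feats)

    def predict(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        return np.argmax(self.predict_logits(x, batch_size), axis=1)


def build_model(spec: FeatureExtractorSpec, n_classes: int = 2,
                seed: int = 0) -> PVAModel:
    """Construct a GAP-headed model with the named trunk."""
    rng = np.random.default_rng(seed)
    extractor = archs.build_extractor(spec.name, rng)
    head = Dense(spec.feature_dim, n_classes, rng=rng, name="head")
    model = PVAModel(spec=spec, extractor=extractor, gap=GlobalAvgPool(),
                     head=head)
    model.n_params = count_parameters(model)
    return model


def count_parameters(model: PVAModel) -> int:
    """Total parameter elements, trainable plus batch-norm statistics."""
    return model.extractor.n_params() + model.head.n_params()


def _as_batch(images) -> np.ndarray:
    if isinstance(images, np.ndarray):
        x = images
    else:
        x = np.stack([im.pixels if hasattr(im, "pixels") else im
                      for im in images])
    if x.ndim == 3:
        x = x[None]
    if x.shape[1:] != (IMG_SIZE, IMG_SIZE, 3):
        raise ValueError(f"images must be (N,{IMG_SIZE},{IMG_SIZE},3), "
                         f"got {x.shape}")
    return x.astype(np.float32)


def extract_features(model: PVAModel, images, batch_size: int = 32) -> np.ndarray:
    """GAP feature matrix (n x feature_dim) for a batch of fused images."""
    x = _as_batch(images)
    out = []
    for start in range(0, len(x), batch_size):
        maps = model.extractor.forward(x[start:start + batch_size])
        out.append(model.gap.forward(maps))
    return np.concatenate(out, axis=0)


def feature_maps(model: PVAModel, images) -> np.ndarray:
    """Last-convolution spatial feature maps (n, h, w, feature_dim)."""
    return model.extractor.forward(_as_batch(images))


# ---------------------------------------------------------------------------
# source task: procedurally drawn curve shapes

SOURCE_CLASSES = ("sine", "square", "ramp", "bump", "damped")


def _source_curve(kind: str, rng: np.random.Generator) -> np.ndarray:
    t = np.linspace(0, 1, IMG_SIZE)
    freq = rng.uniform(1.0, 4.0)
    phase = rng.uniform(0, 2 * np.pi)
    if kind == "sine":
        y = np.sin(2 * np.pi * freq * t + phase)
    elif kind == "square":
        y = np.tanh(8.0 * np.sin(2 * np.pi * freq * t + phase))
    elif kind == "ramp":
        y = (freq * t + phase / (2 * np.pi)) % 1.0
    elif kind == "bump":
        c = rng.uniform(0.2, 0.8)
        w = rng.uniform(0.03, 0.15)
        y = np.exp(-0.5 * ((t - c) / w) ** 2)
    elif kind == "damped":
        y = np.exp(-3 * t) * np.sin(2 * np.pi * (2 + freq) * t + phase)
    else:
        raise ValueError(kind)
    return y + rng.normal(0, 0.02, IMG_SIZE)


def make_source_dataset(n_per_class: int, seed: int = 0,
                        classes=SOURCE_CLASSES) -> tuple:
    """Render curve-shape images: channels are the curve, its derivative
    and its cumulative integral — the same trace/trace'/trace-integral
    structure the breath images have."""
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for ci, kind in enumerate(classes):
        for _ in range(n_per_class):
            y = _source_curve(kind, rng)
            chans = [y, np.gradient(y), np.cumsum(y)]
            imgs = [rasterize(minmax_normalize(c), role)
                    for c, role in zip(chans, ("P", "F", "V"))]
            xs.append(fuse_channels(*imgs).pixels)
            ys.append(ci)
    xs = np.asarray(xs, np.float32)
    ys = np.asarray(ys)
    order = rng.permutation(len(ys))
    return xs[order], ys[order]


def pretrain_source_task(spec: FeatureExtractorSpec,
                         config: TrainingConfig | None = None,
                         n_per_class: int = 40,
                         classes=SOURCE_CLASSES) -> tuple:
    """Train the trunk on the synthetic source task; returns
    (extractor, history).  The classifier head used for the source task is
    discarded — only the trunk weights transfer."""
    if spec.init != "random":
        raise ValueError("pretraining starts from random initialization")
    config = config or TrainingConfig(max_epochs=10, patience_epochs=3,
                                      stop_after_reductions=1)
    x, y = make_source_dataset(n_per_class, seed=config.seed, classes=classes)
    rng = np.random.default_rng(config.seed)
    extractor = archs.build_extractor(spec.name, rng)
    head = Dense(spec.feature_dim, len(classes), rng=rng)
    net = Sequential([extractor, GlobalAvgPool(), head])
    history = fit(net, x, y, len(classes), config)
    return extractor, history


def load_external_weights(model: PVAModel, path) -> PVAModel:
    """Load trunk weights exported from an external source (pickle of
    name-indexed arrays matching this package's layer order)."""
    with open(path, "rb") as fh:
        arrays = pickle.load(fh)
    tensors = model.extractor.param_tensors(trainable_only=False)
    if len(arrays) != len(tensors):
        raise ValueError(f"weight count mismatch: file has {len(arrays)}, "
                         f"model needs {len(tensors)}")
    for (layer, name, arr), new in zip(tensors, arrays):
        if arr.shape != new.shape:
            raise ValueError(f"shape mismatch for {name}: {arr.shape} vs "
                             f"{new.shape}")
        arr[:] = new
    return model


def build_extractor_raw(name: str, seed: int = 0) -> Sequential:
    """Freshly (randomly) initialized trunk without a head."""
    return archs.build_extractor(name, np.random.default_rng(seed))


def dense_head(feature_dim: int, n_classes: int = 2, seed: int = 0) -> Dense:
    return Dense(feature_dim, n_classes, rng=np.random.default_rng(seed),
                 name="head")


def model_from_extractor(name: str, extractor: Sequential,
                         n_classes: int = 2, seed: int = 0,
                         init: str = "source_pretrained") -> PVAModel:
    """Wrap an existing trunk (pretrained or not) with GAP + dense head."""
    spec = FeatureExtractorSpec(name, init=init)
    model = PVAModel(spec=spec, extractor=extractor, gap=GlobalAvgPool(),
                     head=dense_head(spec.feature_dim, n_classes, seed))
    model.n_params = count_parameters(model)
    return model


def fit_dense_probe(feats: np.ndarray, y: np.ndarray, n_classes: int = 2,
                    config: TrainingConfig | None = None) -> tuple:
    """Train a dense softmax head on frozen features.

    Features are standardized for optimization; the standardization is
    absorbed back into the returned head's affine weights, so the head
    applies directly to raw features.  Returns (head, history).
    """
    config = config or TrainingConfig(max_epochs=60, initial_lr=1e-2,
                                      patience_epochs=10,
                                      stop_after_reductions=1)
    feats = np.asarray(feats, np.float32)
    mu = feats.mean(0)
    sd = feats.std(0) + 1e-8
    z = ((feats - mu) / sd).astype(np.float32)
    head = dense_head(feats.shape[1], n_classes, seed=config.seed)
    history = fit(Sequential([head]), z, y, n_classes, config)
    w = head.w.copy()
    head.w[:] = w / sd[:, None]
    head.b[:] = head.b - (mu / sd) @ w
    return head, history


# ---------------------------------------------------------------------------
# fine-tuning

def fine_tune(model: PVAModel, images, labels,
              config: TrainingConfig | None = None,
              freeze_extractor: bool = True) -> dict:
    """Train the model on labeled fused images; returns the history.

    With ``freeze_extractor`` the trunk weights stay bit-identical and
    only the dense head is trained on cached GAP features; otherwise the
    whole network is trained end to end (chain-structured trunks only).
    30% of the provided data is held out as validation; the learning rate
    drops after ``patience_epochs`` stagnant epochs and training stops on
    continued stagnation, restoring the best-validation weights.
    """
    y = np.asarray(labels)
    if y.dtype.kind in "UO":
        raise ValueError("labels must already be encoded as integers")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    n_classes = model.head.b.shape[0]
    if freeze_extractor:
        feats = extract_features(model, images).astype(np.float32)
        head, history = fit_dense_probe(feats, y, n_classes, config)
        model.head = head
        return history
    x = _as_batch(images)
    return fit(model.full_network(), x, y, n_classes,
               config or TrainingConfig())
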