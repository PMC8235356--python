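"""Class activation maps (CAM) for GAP-headed models.

With global average pooling feeding a dense softmax head, the evidence
for class c localizes as a weighted sum of the last convolutional
feature maps: M_c(x, y) = sum_u w_uc * f_u(x, y).  The raw map lives at
the trunk's output resolution and is bilinearly upsampled to the input
size and min-max normalized for display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import ndimage

from .models import PVAModel, feature_maps
from .preprocess import IMG_SIZE, FusedImage


@dataclass
class ClassActivationMap:
    raw: np.ndarray        # (h, w) at trunk resolution
    upsampled: np.ndarray  # (224, 224) in [0, 1]
    class_index: int


def compute_cam(model: PVAModel, image, class_index: int) -> ClassActivationMap:
    """Weighted sum of last-conv feature maps by the dense-head weights."""
    if not hasattr(model, "head") or model.head is None:
        raise ValueError("CAM requires a dense head")
    if not hasattr(model.head, "w"):
        raise ValueError("CAM requires dense-head weights; an SVM head "
                         "has none")
    w = model.head.w
    if not 0 <= class_index < w.shape[1]:
        raise ValueError(f"class_index must be in [0, {w.shape[1]})")
    maps = feature_maps(model, image)[0]          # (h, w, u)
    raw = maps @ w[:, class_index]                # (h, w)
    zoom = (IMG_SIZE / raw.shape[0], IMG_SIZE / raw.shape[1])
    up = ndimage.zoom(raw, zoom, order=1, grid_mode=True, mode="nearest")
    lo, hi = float(up.min()), float(up.max())
    up = (up - lo) / (hi - lo) if hi > lo else np.zeros_like(up)
    return ClassActivationMap(raw=raw, upsampled=up, class_index=class_index)


_JET_STOPS = np.array([
    (0.0, 0.0, 0.5), (0.0, 0.0, 1.0), (0.0, 1.0, 1.0),
    (1.0, 1.0, 0.0), (1.0, 0.0, 0.0), (0.5, 0.0, 0.0)])


def _heat_colors(v: np.ndarray) -> np.ndarray:
    """Map [0,1] values through a blue->red heat colormap."""
    pos = v * (len(_JET_STOPS) - 1)
    i0 = np.clip(pos.astype(int), 0, len(_JET_STOPS) - 2)
    frac = (pos - i0)[..., None]
    return _JET_STOPS[i0] * (1 - frac) + _JET_STOPS[i0 + 1] * frac


def render_overlay(cam: ClassActivationMap, image, path,
                   alpha: float = 0.4) -> None:
    """Alpha-blend the CAM heatmap over the fused image and save as PNG."""
    pixels = image.pixels if isinstance(image, FusedImage) else np.asarray(image)
    if pixels.shape != (IMG_SIZE, IMG_SIZE, 3):
        raise ValueError("image must be 224x224x3")
    heat = _heat_colors(cam.upsampled)
    blend = (1 - alpha) * pixels + alpha * heat
    arr = np.clip(blend * 255, 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path, format="PNG")


def top_decile_mass_in_columns(cam: ClassActivationMap,
                               col_range: tuple) -> float:
    """Fraction of the top-decile CAM mass falling inside a column range.

    Used to check that the evidence for a detection concentrates where
    the asynchrony actually is (e.g. the expiratory notch columns of an
    ineffective-effort image)."""
    up = cam.upsampled
    thresh = np.quantile(up, 0.9)
    mask = up >= thresh
    lo, hi = col_range
    return float(mask[:, lo:hi].sum() / max(mask.sum(), 1))
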