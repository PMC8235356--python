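"""Per-breath signal-to-image encoding.

Each breath's pressure, flow and volume traces are (1) resampled to a
uniform length of 224 and min-max normalized to [0, 1], (2) plotted into a
224x224 grayscale raster (one column per sample, value 1 at the top), and
(3) fused into a three-channel image with pressure, flow and volume as
channels 0, 1 and 2.

Rendering is deliberately binary (1-pixel Bresenham lines, no
anti-aliasing) so images are bit-identical across platforms.  The default
normalization scope is per breath and per channel, making images invariant
to the absolute signal scale; per-record scope is available for callers
that want amplitudes comparable across breaths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synth import BreathCycle, WaveformRecord

IMG_SIZE = 224

CHANNEL_ROLES = ("P", "F", "V")


@dataclass
class ChannelImage:
    """A single rasterized trace: 224x224, foreground in (0,1], background 0."""

    pixels: np.ndarray
    channel_role: str

    def __post_init__(self) -> None:
        if self.pixels.shape != (IMG_SIZE, IMG_SIZE):
            raise ValueError(f"pixels must be {IMG_SIZE}x{IMG_SIZE}")
        if self.channel_role not in CHANNEL_ROLES:
            raise ValueError(f"channel_role must be one of {CHANNEL_ROLES}")


@dataclass
class FusedImage:
    """224x224x3 tensor with P/F/V as channels 0/1/2, values in [0,1]."""

    pixels: np.ndarray
    label: str = "OTHER"
    cycle_id: int = 0

    def __post_init__(self) -> None:
        if self.pixels.shape != (IMG_SIZE, IMG_SIZE, 3):
            raise ValueError(f"pixels must be {IMG_SIZE}x{IMG_SIZE}x3")


def minmax_normalize(x: np.ndarray) -> np.ndarray:
    """Scale to [0, 1] by (x - min) / (max - min).

    A constant input has no range to normalize; it maps to all zeros with a
    warning rather than dividing by zero.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        warnings.warn("constant input: min-max normalization returns zeros",
                      RuntimeWarning, stacklevel=2)
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def resample_to_length(x: np.ndarray, length: int = IMG_SIZE) -> np.ndarray:
    """Linear interpolation onto ``length`` uniform points over the original
    index range; endpoints are preserved exactly."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples to resample")
    if length < 2:
        raise ValueError("target length must be >= 2")
    src = np.arange(x.size)
    dst = np.linspace(0, x.size - 1, length)
    return np.interp(dst, src, x)


def _value_to_row(v: np.ndarray) -> np.ndarray:
    # row 0 is the top of the image and carries value 1
    return np.floor((1.0 - v) * (IMG_SIZE - 1) + 0.5).astype(int)


def rasterize(x_norm: np.ndarray, channel_role: str = "P") -> ChannelImage:
    """Plot a normalized length-224 sequence as a binary 224x224 trace.

    Column j holds sample j; consecutive samples are joined by Bresenham
    line segments so the trace is 8-connected and every column is covered.
    """
    x_norm = np.asarray(x_norm, dtype=float)
    if x_norm.shape != (IMG_SIZE,):
        raise ValueError(f"input must have length {IMG_SIZE}")
    if np.min(x_norm) < 0 or np.max(x_norm) > 1:
        raise ValueError("values must lie in [0, 1]")
    rows = _value_to_row(x_norm)
    img = np.zeros((IMG_SIZE, IMG_SIZE), dtype=float)
    img[rows[0], 0] = 1.0
    for j in range(1, IMG_SIZE):
        (a0, a1), (b0, b1) = _segment_spans(rows[j] - rows[j - 1])
        r = rows[j - 1]
        img[r + min(a0, a1):r + max(a0, a1) + 1, j - 1] = 1.0
        img[r + min(b0, b1):r + max(b0, b1) + 1, j] = 1.0
    return ChannelImage(pixels=img, channel_role=channel_role)


_SEGMENT_CACHE: dict = {}


def _segment_spans(delta: int) -> tuple:
    """Row spans the Bresenham line (0,0)->(1,delta) covers in each column.

    Returns ((a0,a1),(b0,b1)): inclusive row offsets in the left and right
    columns.  Bresenham output for a one-column step is two contiguous
    vertical runs, so spans fully describe it.
    """
    if delta not in _SEGMENT_CACHE:
        col = {0: [], 1: []}
        for x, y in _bresenham(0, 0, 1, delta):
            col[x].append(y)
        for ys in col.values():  # runs are contiguous and monotone
            assert len(ys) == abs(ys[-1] - ys[0]) + 1
        _SEGMENT_CACHE[delta] = ((col[0][0], col[0][-1]),
                                 (col[1][0], col[1][-1]))
    return _SEGMENT_CACHE[delta]


def _bresenham(x0: int, y0: int, x1: int, y1: int):
    """Integer line from (x0,y0) to (x1,y1), inclusive (8-connected)."""
    dx, dy = abs(x1 - x0), -abs(y1 - y0)
    sx = 1 if x0 < x1 else -1
    sy = 1 if y0 < y1 else -1
    err = dx + dy
    x, y = x0, y0
    while True:
        yield x, y
        if x == x1 and y == y1:
            return
        e2 = 2 * err
        if e2 >= dy:
            err += dy
            x += sx
        if e2 <= dx:
            err += dx
            y += sy


def fuse_channels(p_img: ChannelImage, f_img: ChannelImage,
                  v_img: ChannelImage) -> FusedImage:
    """Stack P/F/V channel images into one 3-channel tensor."""
    for img, role in ((p_img, "P"), (f_img, "F"), (v_img, "V")):
        if img.channel_role != role:
            raise ValueError(
                f"expected channel role {role!r}, got {img.channel_role!r}")
    pixels = np.stack([p_img.pixels, f_img.pixels, v_img.pixels], axis=-1)
    return FusedImage(pixels=pixels)


def cycle_to_image(cycle: BreathCycle, norm_scope: str = "breath",
                   record_ranges: dict | None = None) -> FusedImage:
    """Full per-breath encoding: resample, normalize, rasterize, fuse.

    ``norm_scope='breath'`` (default) normalizes each channel by its own
    per-breath min/max; ``norm_scope='record'`` uses ranges precomputed
    over a whole record (pass ``record_ranges`` mapping channel role to
    (min, max), e.g. from :func:`record_channel_ranges`).
    """
    channels = {"P": cycle.pressure, "F": cycle.flow, "V": cycle.volume}
    imgs = {}
    for role, sig in channels.items():
        x = resample_to_length(sig, IMG_SIZE)
        if norm_scope == "breath":
            x = minmax_normalize(x)
        elif norm_scope == "record":
            if record_ranges is None:
                raise ValueError("record_ranges required for record scope")
            lo, hi = record_ranges[role]
            if hi == lo:
                x = np.zeros_like(x)
            else:
                x = np.clip((x - lo) / (hi - lo), 0.0, 1.0)
        else:
            raise ValueError(f"unknown norm_scope {norm_scope!r}")
        imgs[role] = rasterize(x, channel_role=role)
    fused = fuse_channels(imgs["P"], imgs["F"], imgs["V"])
    fused.label = cycle.label
    fused.cycle_id = cycle.cycle_id
    return fused


def record_channel_ranges(record: WaveformRecord) -> dict:
    """Per-channel (min, max) over all cycles of a record."""
    out = {}
    for role, attr in (("P", "pressure"), ("F", "flow"), ("V", "volume")):
        vals = np.concatenate([getattr(c, attr) for c in record.cycles])
        out[role] = (float(vals.min()), float(vals.max()))
    return out


def record_to_images(record: WaveformRecord, norm_scope: str = "breath") -> list:
    """Encode every cycle of a record; DT events yield two DT images."""
    ranges = record_channel_ranges(record) if norm_scope == "record" else None
    return [cycle_to_image(c, norm_scope=norm_scope, record_ranges=ranges)
            for c in record.cycles]


def images_to_array(images: list) -> tuple:
    """Stack FusedImages into (N,224,224,3) float32 plus label list."""
    x = np.stack([im.pixels for im in images]).astype(np.float32)
    y = [im.label for im in images]
    return x, y
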