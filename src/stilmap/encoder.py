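"""Fixed random convolutional encoder for hot spot map images.

Rendered hot spot maps are resized to 1024 x 1024 RGB and passed through four
3x3 convolution + ReLU + 2x2 max-pool stages with channel widths
(16, 8, 8, 4), taking 1024 x 1024 x 3 down to 64 x 64 x 4 = 16,384 values,
which are flattened into one feature vector per slide.

The filters are *untrained*: they are drawn once from a variance-scaled
normal distribution (He initialization) under a fixed seed and never updated,
so the encoder acts as a deterministic random-projection feature extractor.
Random convolutional features of this kind preserve coarse spatial structure
(where the red/blue mass sits, how clumped it is), which is all the
downstream clustering needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from PIL import Image

__all__ = ["EncoderConfig", "preprocess_map_image", "encode_hotspot_map"]


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture and seed of the fixed random encoder.

    ``channels`` gives the output width of each of the four stages; with the
    defaults the flattened output has length (1024 / 2**4)**2 * 4 = 16,384.
    """

    input_size: int = 1024
    in_channels: int = 3
    channels: tuple[int, ...] = (16, 8, 8, 4)
    kernel: int = 3
    weight_seed: int = 0

    @property
    def n_stages(self) -> int:
        return len(self.channels)

    @property
    def output_length(self) -> int:
        side = self.input_size // (2 ** self.n_stages)
        return side * side * self.channels[-1]

    def make_weights(self) -> list[np.ndarray]:
        """Draw the fixed filter bank: stage weights of shape (k, k, c_in, c_out).

        He-scaled normal (std = sqrt(2 / fan_in)), zero biases; drawn once per
        seed so encoding is reproducible bit-for-bit.
        """
        rng = np.random.default_rng(self.weight_seed)
        weights = []
        c_in = self.in_channels
        for c_out in self.channels:
            fan_in = self.kernel * self.kernel * c_in
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                           size=(self.kernel, self.kernel, c_in, c_out))
            weights.append(w.astype(np.float32))
            c_in = c_out
        return weights


def preprocess_map_image(
    image: Image.Image | np.ndarray,
    size: int = 1024,
    resize_mode: str = "pad",
    background: tuple[int, int, int] = (255, 255, 255),
) -> np.ndarray:
    """Standardize an RGB image to a ``size x size x 3`` float array in [0, 1].

    With ``resize_mode="pad"`` (default) the image is first padded to square
    with the background color so tissue geometry is not stretched; ``"stretch"``
    resizes anisotropically. Resampling is bilinear.
    """
    if isinstance(image, np.ndarray):
        arr = image
        if arr.ndim == 2:
            arr = np.stack([arr] * 3, axis=-1)
        if arr.dtype != np.uint8:
            arr = (np.clip(arr, 0, 1) * 255).round().astype(np.uint8)
        image = Image.fromarray(arr, mode="RGB")
    image = image.convert("RGB")
    w, h = image.size
    if w == 0 or h == 0:
        raise ValueError("cannot preprocess a zero-area image")
    if resize_mode == "pad" and w != h:
        side = max(w, h)
        canvas = Image.new("RGB", (side, side), background)
        canvas.paste(image, ((side - w) // 2, (side - h) // 2))
        image = canvas
    elif resize_mode not in ("pad", "stretch"):
        raise ValueError(f"unknown resize_mode {resize_mode!r}")
    if image.size != (size, size):
        image = image.resize((size, size), Image.BILINEAR)
    return np.asarray(image, dtype=np.float32) / 255.0


def _conv2d_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Zero-padded stride-1 'same' convolution via im2col + matmul.

    ``x``: (H, W, C_in); ``w``: (k, k, C_in, C_out) -> (H, W, C_out).
    """
    k = w.shape[0]
    pad = k // 2
    xp = np.pad(x, ((pad, pad), (pad, pad), (0, 0)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(0, 1))
    # windows: (H, W, C_in, k, k) -> columns (H*W, k*k*C_in) matching w layout
    h, wdt = x.shape[0], x.shape[1]
    cols = windows.transpose(0, 1, 3, 4, 2).reshape(h * wdt, k * k * x.shape[2])
    out = cols @ w.reshape(k * k * w.shape[2], w.shape[3])
    return out.reshape(h, wdt, w.shape[3])


def _maxpool2(x: np.ndarray) -> np.ndarray:
    """2x2 max pooling with stride 2 (dimensions must be even)."""
    h, w, c = x.shape
    return x.reshape(h // 2, 2, w // 2, 2, c).max(axis=(1, 3))


def encode_hotspot_map(
    image: np.ndarray, cfg: EncoderConfig = EncoderConfig()
) -> np.ndarray:
    """Encode a preprocessed image into the fixed-length feature vector.

    Deterministic given ``cfg.weight_seed``. An all-zero image maps to the
    all-zero vector (zero biases + rectifier).
    """
    image = np.asarray(image, dtype=np.float32)
    expected = (cfg.input_size, cfg.input_size, cfg.in_channels)
    if image.shape != expected:
        raise ValueError(f"image shape {image.shape} does not match encoder "
                         f"input {expected}; run preprocess_map_image first")
    x = image
    for w in cfg.make_weights():
        x = _conv2d_same(x, w)
        np.maximum(x, 0.0, out=x)  # ReLU
        x = _maxpool2(x)
    return x.reshape(-1).astype(np.float32)
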