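"""Embedding network contract: image batches in, fixed-width features out.

The memory module is agnostic to the backbone as long as it maps a batch of
images to a (B, H) feature matrix with H divisible by 4.  Any callable
object with ``H``, ``in_channels`` and ``input_size`` attributes satisfies
the contract, so large pretrained CNNs can be plugged in where available.
The package ships a small strided CNN (three patch-convolution stages,
global average pooling, and a linear head) whose parameters are fully
seeded: it trains in seconds on one CPU and is the default backbone for
tests and synthetic experiments.

Images are standardized per image (subtract mean, divide by std) before
entering the backbone; the constants are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .exceptions import ConfigurationError, ValidationError
from .nn import PatchConv, Linear, apply_activation, global_avg_pool, \
    make_linear, make_patch_conv

DEFAULT_INPUT_SIZE = 224
TEST_INPUT_SIZE = 64
DEFAULT_H = 2048


@dataclass
class ImageBatch:
    """Batch of grayscale (or replicated-RGB) images with optional labels.

    ``pixels``: (B, C, S, S) intensities in [0, 1]; ``labels``: (B,) class
    indices or None.
    """

    pixels: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 4 or self.pixels.shape[2] != self.pixels.shape[3]:
            raise ValidationError(
                f"pixels must be (B, C, S, S), got {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("pixel intensities must be finite")
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > 1):
            raise ValidationError("pixel intensities must lie in [0, 1]")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape[0] != self.pixels.shape[0]:
                raise ValidationError("labels length must equal batch size")

    @property
    def size(self) -> int:
        return self.pixels.shape[2]


@dataclass
class FeatureBatch:
    """(B, H) embedding-network outputs."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError(f"features must be 2-D, got {self.values.shape}")
        if self.values.shape[1] % 4 != 0:
            raise ValidationError(
                f"feature dim H={self.values.shape[1]} must be divisible by 4")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("features must be finite")

    @property
    def B(self) -> int:
        return self.values.shape[0]

    @property
    def H(self) -> int:
        return self.values.shape[1]


@dataclass
class FixtureBackbone:
    """Seeded three-stage strided CNN; output dimension H."""

    convs: list[PatchConv]
    head: Linear
    H: int
    in_channels: int = 1
    input_size: int = TEST_INPUT_SIZE
    activation: str = "relu"

    def __call__(self, pixels) -> Tensor:
        """(B, C, S, S) tensor/array -> (B, H) feature tensor."""
        h = pixels if isinstance(pixels, Tensor) else Tensor(pixels)
        for conv in self.convs:
            h = apply_activation(conv(h), self.activation)
        return self.head(global_avg_pool(h))


def make_fixture_backbone(H: int, seed: int, in_channels: int = 1,
                          input_size: int = TEST_INPUT_SIZE,
                          activation: str = "relu") -> FixtureBackbone:
    """Small convolutional backbone with fully seeded parameters."""
    if H % 4 != 0:
        raise ValidationError(f"H must be divisible by 4, got {H}")
    if input_size % 16 != 0:
        raise ValidationError(
            f"fixture backbone needs input size divisible by 16, got {input_size}")
    rng = np.random.default_rng(seed)
    convs = [make_patch_conv(rng, in_channels, 16, patch=4),
             make_patch_conv(rng, 16, 32, patch=2),
             make_patch_conv(rng, 32, 64, patch=2)]
    head = make_linear(rng, 64, H)
    return FixtureBackbone(convs, head, H, in_channels, input_size, activation)


def standardize(pixels: np.ndarray, mean: float | None = None,
                std: float | None = None) -> np.ndarray:
    """Per-image standardization unless fixed constants are supplied."""
    pixels = np.asarray(pixels, dtype=np.float64)
    if mean is not None and std is not None:
        return (pixels - mean) / std
    axes = tuple(range(1, pixels.ndim))
    mu = pixels.mean(axis=axes, keepdims=True)
    sd = pixels.std(axis=axes, keepdims=True)
    return (pixels - mu) / np.maximum(sd, 1e-8)


def forward_backbone(backbone, pixels: np.ndarray,
                     normalize: bool = True) -> Tensor:
    """Differentiable path used inside the training loop."""
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.ndim != 4:
        raise ValidationError(f"expected (B, C, S, S) pixels, got {pixels.shape}")
    if pixels.shape[1] != backbone.in_channels:
        if pixels.shape[1] == 1 and backbone.in_channels == 3:
            pixels = np.repeat(pixels, 3, axis=1)  # grayscale -> replicated RGB
        else:
            raise ConfigurationError(
                f"backbone expects {backbone.in_channels} channels, "
                f"got {pixels.shape[1]}")
    if normalize:
        pixels = standardize(pixels)
    return backbone(pixels)


def embed(images: ImageBatch, backbone, normalize: bool = True) -> FeatureBatch:
    """Map an image batch to (B, H) features (inference path, no gradients)."""
    out = forward_backbone(backbone, images.pixels, normalize)
    features = out.value if isinstance(out, Tensor) else np.asarray(out)
    if features.shape != (images.pixels.shape[0], backbone.H):
        raise ConfigurationError(
            f"backbone produced {features.shape}, expected "
            f"{(images.pixels.shape[0], backbone.H)}")
    return FeatureBatch(features)


# -- batch I/O ----------------------------------------------------------


def load_image_dir(path: str | Path, labels_csv: str | None = "labels.csv",
                   size: int | None = None) -> ImageBatch:
    """Read a directory of grayscale PNGs (plus a labels CSV) into a batch.

    The CSV needs ``filename`` and ``label`` columns; files are read in the
    CSV's row order so batches are reproducible.
    """
    from PIL import Image
    import pandas as pd

    path = Path(path)
    table = pd.read_csv(path / labels_csv)
    pixels, labels = [], []
    for _, row in table.iterrows():
        img = Image.open(path / row["filename"]).convert("L")
        if size is not None:
            img = img.resize((size, size), Image.BILINEAR)
        pixels.append(np.asarray(img, dtype=np.float64)[None, :, :] / 255.0)
        labels.append(int(row["label"]))
    return ImageBatch(np.stack(pixels), np.asarray(labels))


def load_npz_batch(path: str | Path) -> ImageBatch:
    with np.load(path) as data:
        labels = data["labels"] if "labels" in data else None
        return ImageBatch(data["pixels"], labels)


def save_npz_batch(batch: ImageBatch, path: str | Path) -> None:
    if batch.labels is None:
        np.savez_compressed(path, pixels=batch.pixels)
    else:
        np.savez_compressed(path, pixels=batch.pixels, labels=batch.labels)
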