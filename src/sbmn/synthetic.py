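"""Synthetic fixtures: tooth-slice images and separable feature sets.

The clinical data this method targets (CBCT slices of fractured and intact
tooth roots) cannot be redistributed, so the package ships two generators:

* **Tooth-slice images** — a bright root silhouette (crown + root ellipse
  with soft edges) on a dark background.  The fracture class adds a thin
  low-intensity line running roughly parallel to the root axis, mimicking
  the longitudinal morphology of a vertical root fracture.  The intact
  class draws one of three confounder variants — a plain root, a dark
  periapical blob near the apex (emulating apical periodontitis), or a
  horizontal darker band (emulating horizontal bone loss) — so a
  classifier cannot succeed by merely detecting "some dark structure".
  Global mean intensity is re-matched after drawing structures, removing
  luminance as a shortcut feature.

* **Feature sets** — two isotropic Gaussian clouds in R^H whose mean
  separation is given in units of the within-class standard deviation.
  The Bayes error is the closed form Phi(-separation / 2), which calibrates
  what accuracy a correct implementation should reach.

These fixtures exercise the network end to end; they do not model CBCT
physics (beam hardening, partial-volume blur) or 3-D anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .embedding import FeatureBatch, ImageBatch
from .exceptions import ValidationError

VRF_LABEL = 1       # positive class: fractured root
NONVRF_LABEL = 0

CONFOUNDERS = ("plain", "periapical_blob", "bone_loss_band")


@dataclass
class SynthImageConfig:
    size: int = 64
    fracture_width_px: int = 2          # 1..3
    fracture_contrast: float = 0.5      # relative intensity drop on the line
    confounder_mix: tuple = (0.34, 0.33, 0.33)  # plain, blob, band
    noise_sd: float = 0.05
    background: float = 0.1
    root_intensity: float = 0.8

    def __post_init__(self):
        if self.fracture_width_px < 1:
            raise ValidationError("fracture_width_px must be >= 1")
        if abs(sum(self.confounder_mix) - 1.0) > 1e-9:
            raise ValidationError("confounder mix probabilities must sum to 1")
        if self.size < 32 or self.size > 224:
            raise ValidationError("size must lie in [32, 224]")


@dataclass
class SynthFeatureConfig:
    H: int = 64
    separation: float = 4.0   # distance between class means, in sd units
    sd: float = 1.0
    n_per_class: int = 400
    seed: int = 0

    def __post_init__(self):
        if self.H % 4 != 0:
            raise ValidationError(f"H must be divisible by 4, got {self.H}")
        if self.separation < 0:
            raise ValidationError("separation must be >= 0")


def _soft_ellipse(S: int, cx: float, cy: float, ax: float, ay: float,
                  edge: float = 1.5) -> np.ndarray:
    """Smooth-edged ellipse mask in [0, 1]."""
    yy, xx = np.mgrid[0:S, 0:S].astype(np.float64)
    f = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2
    # linear falloff over ~`edge` pixels around the boundary f = 1
    w = edge / min(ax, ay)
    return np.clip((1.0 + w - f) / (2.0 * w), 0.0, 1.0)


def _render_root(S: int, rng: np.random.Generator, cfg: SynthImageConfig):
    """Base silhouette: crown ellipse atop an elongated root ellipse."""
    jitter = lambda scale: 1.0 + rng.uniform(-scale, scale)
    cx = S * (0.5 + rng.uniform(-0.04, 0.04))
    crown = _soft_ellipse(S, cx, S * 0.24 * jitter(0.06),
                          S * 0.21 * jitter(0.1), S * 0.15 * jitter(0.1))
    root_cy, root_ay = S * 0.58 * jitter(0.04), S * 0.30 * jitter(0.08)
    root_ax = S * 0.12 * jitter(0.12)
    root = _soft_ellipse(S, cx, root_cy, root_ax, root_ay)
    silhouette = np.maximum(crown, root)
    img = cfg.background + (cfg.root_intensity - cfg.background) * silhouette
    interior = root >= 0.999
    return img, interior, (cx, root_cy, root_ax, root_ay)


def _draw_fracture(img: np.ndarray, interior: np.ndarray, geom,
                   rng: np.random.Generator, cfg: SynthImageConfig) -> np.ndarray:
    """Thin dark line roughly parallel to the root axis, clipped to the root."""
    S = img.shape[0]
    cx, cy, ax_, ay_ = geom
    y0 = max(0, int(cy - 0.9 * ay_))
    y1 = min(S - 1, int(cy + 0.9 * ay_))
    x = cx + rng.uniform(-0.3, 0.3) * ax_
    slant = rng.uniform(-0.15, 0.15)
    half = cfg.fracture_width_px / 2.0
    mask = np.zeros_like(img)
    for y in range(y0, y1 + 1):
        x += slant + rng.normal(0.0, 0.25)
        xi = int(np.clip(round(x), 1, S - 2))  # clip endpoints to the frame
        lo, hi = int(np.floor(xi - half)), int(np.ceil(xi + half))
        for c in range(max(0, lo), min(S, hi + 1)):
            cover = np.clip(half + 0.5 - abs(c - x), 0.0, 1.0)
            mask[y, c] = max(mask[y, c], cover)
    mask *= interior
    return img * (1.0 - cfg.fracture_contrast * mask)


def _draw_periapical_blob(img, geom, rng, cfg):
    S = img.shape[0]
    cx, cy, ax_, ay_ = geom
    bx = cx + rng.uniform(-0.4, 0.4) * ax_
    by = min(S - 2.0, cy + ay_ * rng.uniform(0.75, 1.0))
    r = S * rng.uniform(0.05, 0.09)
    yy, xx = np.mgrid[0:S, 0:S].astype(np.float64)
    blob = np.exp(-((xx - bx) ** 2 + (yy - by) ** 2) / (2.0 * r * r))
    return img * (1.0 - 0.5 * blob)


def _draw_bone_loss_band(img, geom, rng, cfg):
    S = img.shape[0]
    _, cy, _, ay_ = geom
    yc = cy + rng.uniform(-0.5, 0.2) * ay_
    h = S * rng.uniform(0.04, 0.08)
    yy = np.arange(S, dtype=np.float64)
    band = np.exp(-((yy - yc) ** 2) / (2.0 * h * h))[:, None]
    return img * (1.0 - 0.35 * band)


def generate_tooth_image(class_label: int, cfg: SynthImageConfig,
                         seed: int) -> np.ndarray:
    """One (S, S) grayscale slice in [0, 1]; deterministic per seed."""
    rng = np.random.default_rng(seed)
    img, interior, geom = _render_root(cfg.size, rng, cfg)
    target_mean = img.mean()
    if class_label == VRF_LABEL:
        img = _draw_fracture(img, interior, geom, rng, cfg)
    elif class_label == NONVRF_LABEL:
        variant = rng.choice(len(CONFOUNDERS), p=np.asarray(cfg.confounder_mix))
        if CONFOUNDERS[variant] == "periapical_blob":
            img = _draw_periapical_blob(img, geom, rng, cfg)
        elif CONFOUNDERS[variant] == "bone_loss_band":
            img = _draw_bone_loss_band(img, geom, rng, cfg)
    else:
        raise ValidationError(f"class_label must be 0 or 1, got {class_label}")
    img = img + (target_mean - img.mean())  # luminance matched across classes
    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_image_dataset(n_per_class: int, cfg: SynthImageConfig,
                           seed: int) -> ImageBatch:
    """Balanced, shuffled two-class image batch (fracture label = 1)."""
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for i in range(n_per_class):
        images.append(generate_tooth_image(NONVRF_LABEL, cfg, seed=int(rng.integers(2 ** 31))))
        labels.append(NONVRF_LABEL)
        images.append(generate_tooth_image(VRF_LABEL, cfg, seed=int(rng.integers(2 ** 31))))
        labels.append(VRF_LABEL)
    order = rng.permutation(len(images))
    pixels = np.stack(images)[order][:, None, :, :]
    return ImageBatch(pixels, np.asarray(labels)[order])


def generate_feature_dataset(cfg: SynthFeatureConfig):
    """Two Gaussian clouds in R^H; returns (FeatureBatch, labels), shuffled."""
    rng = np.random.default_rng(cfg.seed)
    direction = rng.standard_normal(cfg.H)
    direction /= np.linalg.norm(direction)
    offset = 0.5 * cfg.separation * cfg.sd * direction
    x0 = rng.normal(0.0, cfg.sd, (cfg.n_per_class, cfg.H)) - offset
    x1 = rng.normal(0.0, cfg.sd, (cfg.n_per_class, cfg.H)) + offset
    X = np.vstack([x0, x1])
    y = np.concatenate([np.zeros(cfg.n_per_class, dtype=int),
                        np.ones(cfg.n_per_class, dtype=int)])
    order = rng.permutation(X.shape[0])
    return FeatureBatch(X[order]), y[order]


def bayes_accuracy(cfg: SynthFeatureConfig) -> float:
    """Optimal accuracy for the two-Gaussian configuration: Phi(sep / 2)."""
    return float(norm.cdf(cfg.separation / 2.0))
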