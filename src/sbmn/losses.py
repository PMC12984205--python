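"""The three-term training objective.

L_total = lambda_cls * L_cls + lambda_sim * L_sim + lambda_remake * L_remake

* L_cls    -- cross-entropy between the softmax-normalized class scores and
              the ground-truth label, averaged over the batch;
* L_sim    -- binary cross-entropy between each class module's sim_bar
              evidence and the one-hot label, summed over samples and
              averaged over classes (keeps each memory set aligned with its
              own class);
* L_remake -- mean squared error between the features rebuilt from memory
              and the original embedding features.

All weights default to 1 and live in [0, 1].  Probabilities and evidences
are clamped at CLAMP_EPS before the log so degenerate predictions yield a
large finite loss rather than an infinity; clamping events are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, as_tensor
from .exceptions import ValidationError

logger = logging.getLogger(__name__)

CLAMP_EPS = 1e-7


@dataclass
class LossWeights:
    lambda_cls: float = 1.0
    lambda_sim: float = 1.0
    lambda_remake: float = 1.0

    def __post_init__(self):
        for name in ("lambda_cls", "lambda_sim", "lambda_remake"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class LossReport:
    total: float
    cls: float
    sim: float
    remake: float
    N: int


def _clamped_log(p: Tensor) -> Tensor:
    if np.any(p.value <= CLAMP_EPS):
        # saturated sigmoids land here routinely once training sharpens,
        # so this is not worth a user-facing warning
        logger.debug("loss input clamped at %g (%d entries)",
                     CLAMP_EPS, int(np.sum(p.value <= CLAMP_EPS)))
    return ad.log(ad.clip_min(p, CLAMP_EPS))


def one_hot(labels: np.ndarray, k: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.size and (labels.min() < 0 or labels.max() >= k):
        raise ValidationError(f"labels must lie in 0..{k - 1}")
    eye = np.zeros((labels.shape[0], k))
    eye[np.arange(labels.shape[0]), labels] = 1.0
    return eye


def classification_loss(probabilities, labels) -> Tensor:
    """Mean over the batch of -log p(true class)."""
    probabilities = as_tensor(probabilities)
    B, k = probabilities.shape
    onehot = Tensor(one_hot(labels, k))
    picked = ad.tsum(ad.mul(probabilities, onehot), axis=1)     # (B,)
    return ad.neg(ad.tmean(_clamped_log(picked)))


def similarity_loss(sim_bar, onehot_labels, normalize: bool = False) -> Tensor:
    """Binary cross-entropy of each class evidence against the one-hot label.

    Summed over samples, averaged over the k classes (the printed form);
    ``normalize=True`` additionally divides by the number of samples.
    """
    s = as_tensor(sim_bar)
    y = as_tensor(onehot_labels)
    if s.shape != y.shape:
        raise ValidationError(
            f"sim_bar shape {s.shape} does not match labels {y.shape}")
    _, k = s.shape
    pos = ad.mul(y, _clamped_log(s))
    neg_ = ad.mul(ad.sub(Tensor(np.ones(s.shape)), y),
                  _clamped_log(ad.sub(Tensor(np.ones(s.shape)), s)))
    total = ad.tsum(ad.add(pos, neg_))
    loss = ad.scale(total, -1.0 / k)
    if normalize:
        loss = ad.scale(loss, 1.0 / s.shape[0])
    return loss


def remake_loss(remake_x, x) -> Tensor:
    """Mean squared reconstruction error, averaged over batch and channels."""
    remake_x, x = as_tensor(remake_x), as_tensor(x)
    if remake_x.shape != x.shape:
        raise ValidationError(
            f"shape mismatch: remake {remake_x.shape} vs features {x.shape}")
    return ad.tmean(ad.square(ad.sub(remake_x, x)))


def total_loss(cls: Tensor, sim: Tensor, remake: Tensor,
               weights: LossWeights, N: int) -> tuple[Tensor, LossReport]:
    """Weighted sum; returns the differentiable total plus a numeric report."""
    total = ad.add(
        ad.add(ad.scale(cls, weights.lambda_cls),
               ad.scale(sim, weights.lambda_sim)),
        ad.scale(remake, weights.lambda_remake))
    report = LossReport(total=float(total.value), cls=float(cls.value),
                        sim=float(sim.value), remake=float(remake.value), N=N)
    return total, report
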