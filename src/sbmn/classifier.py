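"""Similarity-based classifier: predictions from feature/memory similarity.

Instead of a fully connected head, each sample's class score is the gated
similarity between its embedding and the (modified) memory of that class:
keys for both sides come from a lightweight projection, the pairwise scores
pass through a sigmoid, and the average over memory slots is the class
evidence.  Softmax over classes turns the evidence into probabilities; the
label is the argmax with ties resolved to the smallest class index, so a
fully uninformative memory (e.g. an all-zero bank) collapses every
prediction onto class 0.

During training the classifier sees the memories the module stack just
modified (keeping the bank trainable through backpropagation); at test time
it sees the frozen bank only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, as_tensor
from .exceptions import StateError, ValidationError
from .memory import CategoryMemory
from .module import BasicModuleParams, Calibration, make_calibration, \
    similarity_gate
from .nn import Linear, make_linear


@dataclass
class ClassifierParams:
    """Key projection owned by the classifier (shared across classes).

    When ``reuse_modules`` is set the classifier instead scores through the
    per-class modules' own head encoders.
    """

    E_K: Linear | None              # H -> H/4
    E_V: Linear | None              # H -> H/2 (completes the gate pipeline)
    similarity_fn: str = "dot"
    reuse_modules: bool = False
    modules: list[BasicModuleParams] | None = None
    cal: "Calibration | None" = None  # shared across classes


@dataclass
class Prediction:
    scores: Tensor         # (B, k) sim_bar per class, entries in (0, 1)
    probabilities: Tensor  # (B, k) softmax over classes
    labels: np.ndarray     # (B,) argmax, ties -> smallest index


def make_classifier_params(rng: np.random.Generator, H: int,
                           similarity_fn: str = "dot") -> ClassifierParams:
    if H % 4 != 0:
        raise ValidationError(f"H must be divisible by 4, got {H}")
    return ClassifierParams(E_K=make_linear(rng, H, H // 4),
                            E_V=make_linear(rng, H, H // 2),
                            similarity_fn=similarity_fn,
                            cal=make_calibration())


def make_reuse_classifier_params(modules: list[BasicModuleParams],
                                 similarity_fn: str = "dot") -> ClassifierParams:
    return ClassifierParams(E_K=None, E_V=None, similarity_fn=similarity_fn,
                            reuse_modules=True, modules=modules)


def _class_score(x: Tensor, m_t: Tensor, params: ClassifierParams,
                 t: int) -> Tensor:
    """Mean-sigmoid gated similarity of every sample against class t's memory."""
    if params.reuse_modules:
        if params.modules is None:
            raise ValidationError("reuse_modules set but no modules attached")
        head_scores = []
        for head in params.modules[t].heads:
            bundle = similarity_gate(head.E_K(x), head.E_K(m_t),
                                     head.E_V(x), head.E_V(m_t),
                                     params.similarity_fn,
                                     calibration=head.cal)
            head_scores.append(bundle.sim_bar)
        total = head_scores[0]
        for s in head_scores[1:]:
            total = ad.add(total, s)
        return ad.scale(total, 1.0 / len(head_scores))
    bundle = similarity_gate(params.E_K(x), params.E_K(m_t),
                             params.E_V(x), params.E_V(m_t),
                             params.similarity_fn, calibration=params.cal)
    return bundle.sim_bar


def classify(x, mod_m, params: ClassifierParams, mode: str = "test",
             memory: CategoryMemory | None = None) -> Prediction:
    """Score a feature batch against per-class memory slices.

    ``mod_m`` is a list of k (M, H) arrays/tensors: in train mode the
    current step's modified memories, in test mode the frozen bank's slices.
    Passing the bank itself in test mode asserts it is actually frozen.
    """
    if mode not in ("train", "test"):
        raise ValidationError(f"mode must be 'train' or 'test', got {mode!r}")
    if mode == "test" and memory is not None and not memory.frozen:
        raise StateError("test-mode classification requires a frozen memory bank")
    x = as_tensor(x)
    cols = []
    for t, slice_t in enumerate(mod_m):
        score_t = _class_score(x, as_tensor(slice_t), params, t)
        cols.append(ad.reshape(score_t, (-1, 1)))
    scores = ad.concat(cols, axis=1)
    probabilities = ad.softmax(scores, axis=1)
    labels = _argmax_first(scores.value)
    return Prediction(scores, probabilities, labels)


def _argmax_first(scores: np.ndarray) -> np.ndarray:
    # np.argmax returns the first maximal index, i.e. the lowest class wins ties
    return np.argmax(scores, axis=1)


def predict_labels(p: Prediction) -> np.ndarray:
    """Deterministic argmax labels; ties resolve to the smallest class index."""
    scores = p.scores.value if isinstance(p.scores, Tensor) else np.asarray(p.scores)
    if scores.shape[0] == 0:
        raise ValidationError("cannot predict labels for an empty batch")
    if not np.all(np.isfinite(scores)):
        raise ValidationError("scores must be finite")
    return _argmax_first(scores)
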