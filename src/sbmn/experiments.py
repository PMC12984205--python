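"""Analysis harnesses probing what the category memory has learned.

* **Memory manipulation** — evaluate a trained, frozen model after
  replacing the bank with zeros, a single class's slots, a fresh random
  draw (repeated, since single draws are uninformative), or the two class
  slices swapped.  A memory-driven classifier should collapse to constant
  predictions under zeroed/cloned banks and invert its decisions under a
  swap; the intact bank must reproduce the standard evaluation exactly.

* **Similarity-function ablation** — cross-validate the same data and
  folds under dot, cosine, Pearson and negative-Euclidean gating.

* **Channel scatter** — pair each feature channel of an encoded sample
  (the four heads' key projections concatenated, length H) with the
  corresponding channel of the slot-averaged encoded memory, and measure
  the Pearson correlation.  Same-class pairs through a trained module
  should align along Y=X; different-class pairs anti-align; pairs drawn
  from two different class modules should decorrelate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .embedding import ImageBatch, forward_backbone
from .exceptions import ValidationError
from .memory import CategoryMemory, manipulate
from .metrics import MetricTable
from .module import encoded_keys
from .training import SBMNModel, TrainConfig, asdict_cfg, cross_validate, evaluate

SCATTER_KINDS = ("intra_class", "inter_class", "inter_module")


@dataclass
class ManipulationReport:
    """Per-mode metric tables and per-class recalls; 'intact' is baseline."""

    modes: dict = field(default_factory=dict)       # name -> MetricTable dict
    per_class_recall: dict = field(default_factory=dict)
    random_repeats: list = field(default_factory=list)


@dataclass
class ScatterReport:
    kind: str
    x: np.ndarray   # (H,) per-channel values of the encoded sample
    y: np.ndarray   # (H,) per-channel values of the encoded memory
    r: float        # Pearson correlation over the H channel pairs


def _per_class_recall(labels_true, labels_pred, k: int) -> dict:
    yt, yp = np.asarray(labels_true), np.asarray(labels_pred)
    out = {}
    for c in range(k):
        mask = yt == c
        out[f"class{c}"] = float(np.mean(yp[mask] == c)) if mask.any() else float("nan")
    return out


def run_manipulation(model: SBMNModel, memory: CategoryMemory, test_data,
                     test_labels: np.ndarray, repeats: int = 10,
                     seed: int = 0) -> ManipulationReport:
    """Evaluate the frozen classifier under each manipulated bank.

    The supplied bank is never mutated; every mode works on a frozen copy.
    """
    if not memory.frozen:
        raise ValidationError("manipulation experiments need a frozen bank")
    test_labels = np.asarray(test_labels, dtype=int)
    report = ManipulationReport()
    bank_before = memory.bank.copy()

    def run(bank: CategoryMemory, name: str):
        bank.freeze()
        pred, _, _, table = evaluate(model, bank, test_data, test_labels)
        report.modes[name] = table.as_dict()
        report.per_class_recall[name] = _per_class_recall(test_labels, pred,
                                                          memory.k)
        return table

    run(memory.copy(), "intact")
    run(manipulate(memory, "zeros"), "zeros")
    run(manipulate(memory, "single_class", source_class=0), "single_class")
    if memory.k == 2:
        run(manipulate(memory, "swap"), "swap")
    rng = np.random.default_rng(seed)
    for i in range(repeats):
        t = run(manipulate(memory, "random", seed=int(rng.integers(2 ** 31))),
                f"random_{i}")
        report.random_repeats.append(t.accuracy)
    assert np.array_equal(memory.bank, bank_before)
    return report


def run_similarity_ablation(data, labels: np.ndarray, cfg: TrainConfig,
                            fns=("dot", "cosine", "pearson", "euclidean"),
                            k_folds: int = 5) -> dict:
    """One cross-validated metric table per similarity function.

    The fold assignment and all seeds are shared across functions, so rows
    differ only in the gating similarity.
    """
    tables = {}
    for fn in fns:
        fn_cfg = TrainConfig(**{**asdict_cfg(cfg), "similarity_fn": fn})
        cv = cross_validate(data, labels, fn_cfg, k_folds=k_folds)
        tables[fn] = cv["mean"]
    return tables


def _sample_features(model: SBMNModel, sample) -> np.ndarray:
    """One sample -> (1, H) embedding (images go through the backbone)."""
    arr = np.asarray(sample.pixels if isinstance(sample, ImageBatch) else sample,
                     dtype=np.float64)
    if arr.ndim >= 3:  # image input
        if arr.ndim == 3:
            arr = arr[None]
        if model.backbone is None:
            raise ValidationError("image input requires a model with a backbone")
        return forward_backbone(model.backbone, arr).value[:1]
    return arr.reshape(1, -1)


def channel_scatter(model: SBMNModel, memory: CategoryMemory, sample,
                    sample_class: int, kind: str) -> ScatterReport:
    """Channel-pair analysis of one sample against the encoded memory.

    intra_class  -- sample and memory of ``sample_class`` through that
                    class's own module;
    inter_class  -- sample pushed through the *other* class's module and
                    paired with that class's memory;
    inter_module -- sample keys from its own module vs the other class's
                    memory encoded by the other module (independent
                    encoders, so channels should decorrelate).
    """
    if kind not in SCATTER_KINDS:
        raise ValidationError(f"kind must be one of {SCATTER_KINDS}")
    if memory.k != 2:
        raise ValidationError("channel scatter analysis is defined for k=2")
    x = _sample_features(model, sample)
    other = 1 - sample_class
    if kind == "intra_class":
        x_K, hid_K = encoded_keys(x, memory.class_slice(sample_class),
                                  model.modules[sample_class])
    elif kind == "inter_class":
        x_K, hid_K = encoded_keys(x, memory.class_slice(other),
                                  model.modules[other])
    else:  # inter_module
        x_K, _ = encoded_keys(x, memory.class_slice(sample_class),
                              model.modules[sample_class])
        _, hid_K = encoded_keys(x, memory.class_slice(other),
                                model.modules[other])
    x_K = x_K.ravel()
    r = float(np.corrcoef(x_K, hid_K)[0, 1])
    return ScatterReport(kind=kind, x=x_K, y=hid_K, r=r)


def feature_scatter(model: SBMNModel, image_a, image_b) -> ScatterReport:
    """Embedding-vs-embedding channel pairs for an image pair (no memory).

    Works for untrained backbones too; used to compare how training shapes
    per-channel consistency between same-class and cross-class images.
    """
    xa = _sample_features(model, image_a).ravel()
    xb = _sample_features(model, image_b).ravel()
    return ScatterReport(kind="feature_pair", x=xa, y=xb,
                         r=float(np.corrcoef(xa, xb)[0, 1]))
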