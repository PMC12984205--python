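"""Training protocol: SGD with step-decay, per-step memory commit,
augmentation, and stratified five-fold cross-validation.

One optimizer step runs embedding -> per-class memory modules ->
similarity classifier, backpropagates the three-term loss, applies SGD
with momentum and weight decay, and then commits the step's modified
memories into the bank (gradient-decoupled).  The bank is therefore
rewritten exactly once per step and never during evaluation.

The learning rate follows lr(e) = max(lr_min, lr0 * 0.95^floor(e / 5)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .classifier import ClassifierParams, classify, make_classifier_params, \
    make_reuse_classifier_params, predict_labels
from .embedding import FixtureBackbone, ImageBatch, forward_backbone, \
    make_fixture_backbone
from .exceptions import NumericalError, ValidationError
from .losses import LossReport, LossWeights, classification_loss, one_hot, \
    remake_loss, similarity_loss, total_loss
from .memory import CategoryMemory, commit_update, init_memory
from .metrics import ConfusionMatrix, MetricTable, confusion, mean_metric_table, \
    metric_table
from .module import BasicModuleParams, forward_sbmn, make_module_params
from .nn import collect_params, zero_grads


@dataclass
class TrainConfig:
    """Optimizer, schedule and loss settings (defaults follow the protocol)."""

    lr0: float = 0.005
    momentum: float = 0.9
    weight_decay: float = 0.0004
    batch_size: int = 32
    decay_factor: float = 0.95
    decay_every: int = 5          # epochs between learning-rate decays
    lr_min: float = 0.00001
    epochs: int = 30
    seed: int = 0
    M: int = 16                   # memory slots per class
    similarity_fn: str = "dot"
    activation: str = "relu"
    weights: LossWeights = field(default_factory=LossWeights)
    normalize_sim_loss: bool = False
    classifier_reuse: bool = False
    augment: bool = False         # geometric/photometric jitter on image batches
    grad_clip: float = 5.0        # global gradient-norm ceiling; 0 disables

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")
        if self.lr0 < self.lr_min:
            raise ValidationError("lr0 must not be below lr_min")


def lr_at(epoch: int, cfg: TrainConfig) -> float:
    """Step-decayed learning rate, floored at lr_min."""
    if epoch < 0:
        raise ValidationError("epoch must be non-negative")
    return max(cfg.lr_min, cfg.lr0 * cfg.decay_factor ** (epoch // cfg.decay_every))


# -- augmentation -------------------------------------------------------


def augment(image: np.ndarray, seed_or_rng, brightness: float = 0.5,
            contrast: float = 0.5, saturation: float = 0.5, hue: float = 0.3,
            max_rotation: float = 90.0, p_flip: float = 0.5,
            enabled: bool = True, return_params: bool = False):
    """Random flips, photometric jitter and rotation for one training image.

    ``image`` is (C, S, S) or (S, S) in [0, 1].  Saturation and hue only
    apply to 3-channel inputs; on grayscale they are no-ops.  With
    ``enabled=False`` (evaluation phase) the image passes through unchanged.
    """
    from scipy.ndimage import rotate as nd_rotate

    img = np.asarray(image, dtype=np.float64)
    if not enabled:
        return (img.copy(), {}) if return_params else img.copy()
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) \
        else np.random.default_rng(seed_or_rng)
    squeeze = img.ndim == 2
    if squeeze:
        img = img[None]
    params = {"hflip": bool(rng.random() < p_flip),
              "vflip": bool(rng.random() < p_flip),
              "brightness": rng.uniform(1.0 - brightness, 1.0 + brightness),
              "contrast": rng.uniform(1.0 - contrast, 1.0 + contrast),
              "saturation": rng.uniform(1.0 - saturation, 1.0 + saturation),
              "hue": rng.uniform(-hue, hue),
              "angle": rng.uniform(-max_rotation, max_rotation)}
    if params["hflip"]:
        img = img[:, :, ::-1]
    if params["vflip"]:
        img = img[:, ::-1, :]
    img = img * params["brightness"]
    img = (img - img.mean()) * params["contrast"] + img.mean()
    if img.shape[0] == 3:  # saturation/hue are color ops: no-ops on grayscale
        gray = img.mean(axis=0, keepdims=True)
        img = gray + params["saturation"] * (img - gray)
        img = _shift_hue(img, params["hue"])
    img = np.stack([nd_rotate(c, params["angle"], reshape=False, order=1,
                              mode="constant", cval=float(c.min()))
                    for c in img])
    img = np.clip(img, 0.0, 1.0)
    img = img[0] if squeeze else img
    return (img, params) if return_params else img


def _shift_hue(img: np.ndarray, shift: float) -> np.ndarray:
    from skimage.color import hsv2rgb, rgb2hsv

    hsv = rgb2hsv(np.clip(img, 0.0, 1.0).transpose(1, 2, 0))
    hsv[..., 0] = (hsv[..., 0] + shift) % 1.0
    return hsv2rgb(hsv).transpose(2, 0, 1)


# -- model container ----------------------------------------------------


@dataclass
class SBMNModel:
    modules: list[BasicModuleParams]
    classifier: ClassifierParams
    backbone: FixtureBackbone | None
    H: int
    k: int
    similarity_fn: str = "dot"
    activation: str = "relu"

    def parameters(self):
        return collect_params([self.backbone, self.modules, self.classifier])


def build_model(k: int, H: int, seed: int, similarity_fn: str = "dot",
                activation: str = "relu", backbone: FixtureBackbone | None = None,
                with_backbone: bool = False, input_size: int = 64,
                classifier_reuse: bool = False) -> SBMNModel:
    rng = np.random.default_rng(seed)
    if backbone is None and with_backbone:
        backbone = make_fixture_backbone(H, seed=int(rng.integers(2 ** 31)),
                                         input_size=input_size,
                                         activation=activation)
    modules = [make_module_params(rng, H, activation) for _ in range(k)]
    if classifier_reuse:
        clf = make_reuse_classifier_params(modules, similarity_fn)
    else:
        clf = make_classifier_params(rng, H, similarity_fn)
    return SBMNModel(modules, clf, backbone, H, k, similarity_fn, activation)


def clip_grad_norm(params: list[Tensor], max_norm: float) -> float:
    """Rescale all gradients so their joint L2 norm is at most ``max_norm``.

    The memory-replacement recursion can transiently produce very large
    gradients once the gate sharpens; clipping bounds the step size without
    changing the descent direction."""
    total = float(np.sqrt(sum(float(np.sum(p.grad ** 2))
                              for p in params if p.grad is not None)))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale
    return total


class SGD:
    """SGD with classical momentum and decoupled-from-schedule weight decay."""

    def __init__(self, params: list[Tensor], momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = params
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.value) for p in params]

    def step(self, lr: float) -> None:
        for p, v in zip(self.params, self.velocity):
            g = p.grad if p.grad is not None else np.zeros_like(p.value)
            g = g + self.weight_decay * p.value
            v *= self.momentum
            v += g
            p.value = p.value - lr * v


# -- the step and the loop ----------------------------------------------


def _gate_stats(out) -> dict:
    """Per-step diagnostics: mean gate entropy and class evidences."""
    wm = out.head_bundles[0][0].W_m.value
    ent = float(-np.sum(wm * np.log(np.clip(wm, 1e-12, None)), axis=1).mean())
    stats = {"wm_entropy": ent}
    for t in range(out.class_scores.shape[1]):
        stats[f"sim_bar_class{t}"] = float(out.class_scores.value[:, t].mean())
    return stats


def train_step(batch_inputs, batch_labels: np.ndarray, model: SBMNModel,
               memory: CategoryMemory, optimizer: SGD, cfg: TrainConfig,
               lr: float):
    """One forward/backward/commit cycle; returns (memory, LossReport, stats)."""
    if model.backbone is not None:
        x = forward_backbone(model.backbone, batch_inputs)
    else:
        x = Tensor(np.asarray(batch_inputs, dtype=np.float64))
    out = forward_sbmn(x, memory, model.modules, model.similarity_fn,
                       labels=batch_labels)
    pred = classify(x, out.mod_m, model.classifier, mode="train")
    cls_l = classification_loss(pred.probabilities, batch_labels)
    sim_l = similarity_loss(out.class_scores, one_hot(batch_labels, memory.k),
                            normalize=cfg.normalize_sim_loss)
    rem_l = remake_loss(out.remake_x, x)
    total, report = total_loss(cls_l, sim_l, rem_l, cfg.weights,
                               N=len(batch_labels))
    if not np.isfinite(report.total):
        sim0 = out.head_bundles[0][0].sim.value
        raise NumericalError(
            f"non-finite loss {report!r}; gate sim range "
            f"[{np.nanmin(sim0):.3g}, {np.nanmax(sim0):.3g}], stats {_gate_stats(out)}")
    params = model.parameters()
    zero_grads(params)
    total.backward()
    if cfg.grad_clip > 0:
        clip_grad_norm(params, cfg.grad_clip)
    optimizer.step(lr)
    memory = commit_update(memory, [t.value for t in out.mod_m])
    return memory, report, _gate_stats(out)


@dataclass
class TrainResult:
    model: SBMNModel
    memory: CategoryMemory
    log: list[dict]
    config: TrainConfig


def _as_inputs(data):
    """Accepts ImageBatch, FeatureBatch-like, or a raw (N, H) array."""
    if isinstance(data, ImageBatch):
        return data.pixels, True
    values = getattr(data, "values", data)
    return np.asarray(values, dtype=np.float64), False


def fit(data, labels: np.ndarray, cfg: TrainConfig,
        model: SBMNModel | None = None,
        memory: CategoryMemory | None = None) -> TrainResult:
    """Full training run; builds model and memory when not supplied."""
    inputs, is_images = _as_inputs(data)
    labels = np.asarray(labels, dtype=int)
    if inputs.shape[0] != labels.shape[0]:
        raise ValidationError("data and labels disagree in length")
    k = int(labels.max()) + 1
    rng = np.random.default_rng(cfg.seed)
    if model is None:
        H = 64 if is_images else inputs.shape[1]
        model = build_model(k, H, seed=int(rng.integers(2 ** 31)),
                            similarity_fn=cfg.similarity_fn,
                            activation=cfg.activation,
                            with_backbone=is_images,
                            input_size=inputs.shape[-1] if is_images else 64,
                            classifier_reuse=cfg.classifier_reuse)
    if memory is None:
        memory = init_memory(cfg.M, k, model.H, seed=int(rng.integers(2 ** 31)))
    memory.unfreeze()
    optimizer = SGD(model.parameters(), cfg.momentum, cfg.weight_decay)
    log: list[dict] = []
    n = inputs.shape[0]
    for epoch in range(cfg.epochs):
        lr = lr_at(epoch, cfg)
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = inputs[idx]
            if is_images and cfg.augment:
                batch = np.stack([augment(im, rng) for im in batch])
            memory, report, stats = train_step(batch, labels[idx], model,
                                               memory, optimizer, cfg, lr)
            log.append({"epoch": epoch, "step": memory.step, "lr": lr,
                        **asdict(report), **stats})
    memory.freeze()
    return TrainResult(model, memory, log, cfg)


def evaluate(model: SBMNModel, memory: CategoryMemory, data,
             labels: np.ndarray | None = None, batch_size: int = 64,
             positive_class: int = 1):
    """Frozen-memory prediction; with labels also returns the metric table.

    Returns ``(pred_labels, scores)`` or ``(pred_labels, scores, cm, table)``.
    """
    inputs, is_images = _as_inputs(data)
    if not memory.frozen:
        raise ValidationError("evaluation requires a frozen memory bank")
    preds, scores = [], []
    for start in range(0, inputs.shape[0], batch_size):
        chunk = inputs[start:start + batch_size]
        if model.backbone is not None:
            x = forward_backbone(model.backbone, chunk).value
        else:
            x = chunk
        p = classify(x, memory.slices(), model.classifier, mode="test",
                     memory=memory)
        preds.append(predict_labels(p))
        scores.append(p.scores.value)
    pred_labels = np.concatenate(preds)
    score_mat = np.vstack(scores)
    if labels is None:
        return pred_labels, score_mat
    cm = confusion(labels, pred_labels, positive_class)
    return pred_labels, score_mat, cm, metric_table(cm)


# -- cross-validation ---------------------------------------------------


def stratified_folds(labels: np.ndarray, k_folds: int, seed: int):
    """Per-class round-robin assignment after a seeded shuffle.

    Guarantees fold class counts within one sample of each other.
    Returns an (n,) array of fold ids in {0..k_folds-1}.
    """
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    assignment = np.empty(labels.shape[0], dtype=int)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = idx[rng.permutation(idx.size)]
        assignment[idx] = np.arange(idx.size) % k_folds
    return assignment


def cross_validate(data, labels: np.ndarray, cfg: TrainConfig,
                   k_folds: int = 5) -> dict:
    """Train from scratch on each fold; report per-fold and mean metrics."""
    inputs, is_images = _as_inputs(data)
    labels = np.asarray(labels, dtype=int)
    folds = stratified_folds(labels, k_folds, cfg.seed)
    wrap = (lambda a: ImageBatch(a)) if is_images else (lambda a: a)
    per_fold: list[MetricTable] = []
    results = []
    for f in range(k_folds):
        train_idx, test_idx = folds != f, folds == f
        train_labels = labels[train_idx]
        if np.unique(train_labels).size != np.unique(labels).size:
            raise ValidationError(f"fold {f}: a class is absent from training")
        fold_cfg = TrainConfig(**{**asdict_cfg(cfg), "seed": cfg.seed + 1000 + f})
        run = fit(wrap(inputs[train_idx]), train_labels, fold_cfg)
        _, _, cm, table = evaluate(run.model, run.memory,
                                   wrap(inputs[test_idx]), labels[test_idx])
        per_fold.append(table)
        results.append({"fold": f, "n_test": int(test_idx.sum()),
                        **table.as_dict()})
    mean_table = mean_metric_table(per_fold)
    return {"folds": results, "mean": mean_table.as_dict(),
            "per_fold_tables": per_fold, "mean_table": mean_table}


def asdict_cfg(cfg: TrainConfig) -> dict:
    d = asdict(cfg)
    d["weights"] = LossWeights(**d["weights"])
    return d


# -- checkpointing ------------------------------------------------------


def save_model(model: SBMNModel, path: str | Path) -> None:
    """Model parameters + architecture metadata in one npz."""
    path = Path(path)
    params = model.parameters()
    meta = {"H": model.H, "k": model.k, "similarity_fn": model.similarity_fn,
            "activation": model.activation,
            "with_backbone": model.backbone is not None,
            "input_size": model.backbone.input_size if model.backbone else 64,
            "classifier_reuse": model.classifier.reuse_modules,
            "n_params": len(params)}
    arrays = {f"param_{i}": p.value for i, p in enumerate(params)}
    np.savez_compressed(path, meta=json.dumps(meta), **arrays)


def load_model(path: str | Path) -> SBMNModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        model = build_model(meta["k"], meta["H"], seed=0,
                            similarity_fn=meta["similarity_fn"],
                            activation=meta["activation"],
                            with_backbone=meta["with_backbone"],
                            input_size=meta["input_size"],
                            classifier_reuse=meta["classifier_reuse"])
        params = model.parameters()
        if len(params) != meta["n_params"]:
            raise ValidationError("checkpoint does not match the rebuilt model")
        for i, p in enumerate(params):
            stored = data[f"param_{i}"]
            if stored.shape != p.value.shape:
                raise ValidationError(f"parameter {i} shape mismatch")
            p.value = stored.astype(np.float64)
    return model
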