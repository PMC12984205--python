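"""The basic similarity-gated memory module and its per-class stack.

Each class owns an independent module with four heads.  A head projects the
feature batch x (B, H) and the class memory m_t (M, H) through shared linear
maps into keys (dim H/4) and values (dim H/2), scores every sample against
every memory slot, and normalizes the score matrix two ways:

* ``layer_softmax``  -- softmax over the M memory slots (rows sum to 1),
  weighting memory values into per-sample summaries WV_m (B, H/2);
* ``batch_softmax``  -- softmax over the B samples (columns sum to 1),
  weighting sample values into per-slot summaries WV_x (M, H/2).

The same raw scores, squashed by a sigmoid and averaged over slots, give the
per-sample class evidence sim_bar in (0, 1).  A decoder mixes each head's
cross summaries with the same-branch values and fuses the four heads into a
modified feature batch mod_x and a modified class memory mod_m; a separate
remake decoder reconstructs the input features purely from the
memory-weighted summaries, so the memory content can be audited through a
reconstruction loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, as_tensor
from .exceptions import ValidationError
from .memory import CategoryMemory
from .nn import MLP2, Linear, make_linear, make_mlp2

SIMILARITY_FNS = ("dot", "cosine", "pearson", "euclidean")
N_HEADS = 4
_EPS = 1e-12


@dataclass
class Calibration:
    """Learnable affine map applied to raw scores before the sigmoid branch.

    sigsim = sigmoid(exp(log_scale) * sim + bias).  Initialized to the
    identity (log_scale = 0, bias = 0) so the uncalibrated equations are
    recovered at initialization; the positive scale preserves monotonicity.
    Bounded similarity measures (cosine, Pearson, negative Euclidean
    distance) confine the raw scores to a narrow band where the sigmoid
    saturates near 0.5 or below; the calibration lets every measure reach
    informative evidence levels."""

    log_scale: Tensor  # scalar
    bias: Tensor       # scalar

    def __call__(self, sim: Tensor) -> Tensor:
        return ad.add(ad.mul(sim, ad.exp(self.log_scale)), self.bias)


def make_calibration() -> Calibration:
    return Calibration(Tensor(np.zeros(()), requires_grad=True),
                       Tensor(np.zeros(()), requires_grad=True))


@dataclass
class HeadParams:
    """One attention head: shared key/value projections plus its mixer."""

    E_K: Linear  # H -> H/4, applied to both features and memory
    E_V: Linear  # H -> H/2, applied to both features and memory
    f_mix: MLP2  # H -> H -> H
    cal: Calibration = None  # score calibration for the sigmoid branch


@dataclass
class BasicModuleParams:
    """Parameters of one per-class module: 4 heads and the fusion decoders."""

    heads: list[HeadParams]   # exactly 4, mutually independent
    f_dec_x: Linear           # 4H -> H
    f_dec_m: Linear           # 4H -> H
    f_re_dec: Linear          # 2H -> H

    def __post_init__(self):
        if len(self.heads) != N_HEADS:
            raise ValidationError(f"expected {N_HEADS} heads, got {len(self.heads)}")

    @property
    def H(self) -> int:
        return self.f_dec_x.d_out


@dataclass
class GateBundle:
    """Per-head similarity products (all autodiff tensors)."""

    sim: Tensor      # (B, M) raw similarity
    W_m: Tensor      # (B, M), rows sum to 1 (softmax over M)
    W_x: Tensor      # (B, M), columns sum to 1 (softmax over B)
    WV_m: Tensor     # (B, H/2) memory summary per sample
    WV_x: Tensor     # (M, H/2) sample summary per slot
    sim_bar: Tensor  # (B,) mean over M of sigmoid(sim), in (0, 1)


@dataclass
class SBMNOutput:
    """Result of one forward pass through the k-class module stack."""

    mod_x: Tensor                          # (B, H) modified features
    mod_m: list[Tensor]                    # k tensors of shape (M, H)
    class_scores: Tensor                   # (B, k), entries in (0, 1)
    remake_x: Tensor                       # (B, H) features rebuilt from memory
    mod_x_per_class: list[Tensor]          # k tensors (B, H)
    remake_per_class: list[Tensor]         # k tensors (B, H)
    head_bundles: list[list[GateBundle]]   # [class][head] gate diagnostics


def make_head_params(rng: np.random.Generator, H: int,
                     activation: str = "relu") -> HeadParams:
    if H % 4 != 0:
        raise ValidationError(f"H must be divisible by 4, got {H}")
    return HeadParams(E_K=make_linear(rng, H, H // 4),
                      E_V=make_linear(rng, H, H // 2),
                      f_mix=make_mlp2(rng, H, H, H, activation),
                      cal=make_calibration())


def make_module_params(rng: np.random.Generator, H: int,
                       activation: str = "relu") -> BasicModuleParams:
    heads = [make_head_params(rng, H, activation) for _ in range(N_HEADS)]
    return BasicModuleParams(heads=heads,
                             f_dec_x=make_linear(rng, 4 * H, H),
                             f_dec_m=make_linear(rng, 4 * H, H),
                             f_re_dec=make_linear(rng, 2 * H, H))


def encode(x, m_t, head: HeadParams):
    """Project features and one class memory through the head's shared maps.

    Returns ``(K_x, K_m, V_x, V_m)`` with shapes
    (B, H/4), (M, H/4), (B, H/2), (M, H/2).
    """
    x, m_t = as_tensor(x), as_tensor(m_t)
    H = head.E_K.d_in
    if x.shape[1] != H or m_t.shape[1] != H:
        raise ValidationError(
            f"feature/memory dim mismatch: head expects H={H}, "
            f"got x: {x.shape}, m_t: {m_t.shape}")
    return head.E_K(x), head.E_K(m_t), head.E_V(x), head.E_V(m_t)


def _pairwise_similarity(K_x: Tensor, K_m: Tensor, similarity_fn: str) -> Tensor:
    """(B, d) x (M, d) -> (B, M); larger always means more similar."""
    if similarity_fn == "dot":
        return ad.matmul(K_x, ad.transpose(K_m))
    if similarity_fn in ("cosine", "pearson"):
        if similarity_fn == "pearson":
            K_x = ad.sub(K_x, ad.tmean(K_x, axis=1, keepdims=True))
            K_m = ad.sub(K_m, ad.tmean(K_m, axis=1, keepdims=True))
        nx = ad.sqrt(ad.add(ad.tsum(ad.square(K_x), axis=1, keepdims=True), _EPS))
        nm = ad.sqrt(ad.add(ad.tsum(ad.square(K_m), axis=1, keepdims=True), _EPS))
        return ad.matmul(ad.div(K_x, nx), ad.transpose(ad.div(K_m, nm)))
    if similarity_fn == "euclidean":
        # negative distance keeps the "larger = more similar" polarity
        sx = ad.tsum(ad.square(K_x), axis=1, keepdims=True)        # (B, 1)
        sm = ad.reshape(ad.tsum(ad.square(K_m), axis=1), (1, -1))  # (1, M)
        cross = ad.scale(ad.matmul(K_x, ad.transpose(K_m)), -2.0)
        d2 = ad.add(ad.add(sx, sm), cross)
        return ad.neg(ad.sqrt(ad.add(ad.clip_min(d2, 0.0), _EPS)))
    raise ValidationError(
        f"unknown similarity_fn {similarity_fn!r}; choose from {SIMILARITY_FNS}")


def similarity_gate(K_x, K_m, V_x, V_m, similarity_fn: str = "dot",
                    calibration: Calibration | None = None) -> GateBundle:
    """Score, dual-softmax-normalize, and aggregate values both ways.

    ``calibration``, when given, rescales the raw scores before the
    sigmoid/mean evidence branch only; the softmax weightings always act
    on the raw scores."""
    K_x, K_m = as_tensor(K_x), as_tensor(K_m)
    V_x, V_m = as_tensor(V_x), as_tensor(V_m)
    if K_x.shape[1] != K_m.shape[1]:
        raise ValidationError(
            f"key dims differ: {K_x.shape[1]} vs {K_m.shape[1]}")
    sim = _pairwise_similarity(K_x, K_m, similarity_fn)
    W_m = ad.softmax(sim, axis=1)                    # over memory slots
    W_x = ad.softmax(sim, axis=0)                    # over the batch
    WV_m = ad.matmul(W_m, V_m)                       # (B, H/2)
    WV_x = ad.matmul(ad.transpose(W_x), V_x)         # (M, H/2)
    scored = calibration(sim) if calibration is not None else sim
    sim_bar = ad.tmean(ad.sigmoid(scored), axis=1)   # (B,)
    return GateBundle(sim, W_m, W_x, WV_m, WV_x, sim_bar)


def decode(bundles: list[GateBundle], V_x: list[Tensor], V_m: list[Tensor],
           params: BasicModuleParams):
    """Fuse the four heads into modified features and modified memory."""
    if len(bundles) != N_HEADS or len(V_x) != N_HEADS or len(V_m) != N_HEADS:
        raise ValidationError(f"decode needs exactly {N_HEADS} head inputs")
    mixed_x, mixed_m = [], []
    for bundle, vx, vm, head in zip(bundles, V_x, V_m, params.heads):
        mod_x_tilde = ad.concat([bundle.WV_m, vx], axis=1)   # (B, H)
        mod_m_tilde = ad.concat([bundle.WV_x, vm], axis=1)   # (M, H)
        mixed_x.append(head.f_mix(mod_x_tilde))
        mixed_m.append(head.f_mix(mod_m_tilde))
    mod_x = params.f_dec_x(ad.concat(mixed_x, axis=1))       # (B, H)
    mod_m_t = params.f_dec_m(ad.concat(mixed_m, axis=1))     # (M, H)
    return mod_x, mod_m_t


def remake_decode(WV_m: list[Tensor], params: BasicModuleParams) -> Tensor:
    """Rebuild features from the 4 heads' memory-weighted summaries alone."""
    if len(WV_m) != N_HEADS:
        raise ValidationError(f"remake_decode needs {N_HEADS} WV_m arrays")
    return params.f_re_dec(ad.concat(list(WV_m), axis=1))    # (B, 2H) -> (B, H)


def run_basic_module(x, m_t, params: BasicModuleParams,
                     similarity_fn: str = "dot"):
    """One class module end to end.

    Returns ``(mod_x, mod_m_t, sim_bar, remake_x, bundles)`` where sim_bar
    is the mean of the four heads' per-sample scores.
    """
    x, m_t = as_tensor(x), as_tensor(m_t)
    bundles, Vxs, Vms = [], [], []
    for head in params.heads:
        K_x, K_m, V_x, V_m = encode(x, m_t, head)
        bundles.append(similarity_gate(K_x, K_m, V_x, V_m, similarity_fn,
                                       calibration=head.cal))
        Vxs.append(V_x)
        Vms.append(V_m)
    mod_x, mod_m_t = decode(bundles, Vxs, Vms, params)
    remake_x = remake_decode([b.WV_m for b in bundles], params)
    sim_bar = ad.scale(
        ad.add(ad.add(bundles[0].sim_bar, bundles[1].sim_bar),
               ad.add(bundles[2].sim_bar, bundles[3].sim_bar)),
        1.0 / N_HEADS)
    return mod_x, mod_m_t, sim_bar, remake_x, bundles


def _select_rows(per_class: list[Tensor], choice: np.ndarray, k: int) -> Tensor:
    """Row-wise differentiable gather: out[b] = per_class[choice[b]][b]."""
    B = per_class[0].shape[0]
    out = None
    for t in range(k):
        mask = (choice == t).astype(np.float64).reshape(B, 1)
        term = ad.mul(per_class[t], Tensor(mask))
        out = term if out is None else ad.add(out, term)
    return out


def forward_sbmn(x, memory: CategoryMemory,
                 all_params: list[BasicModuleParams],
                 similarity_fn: str = "dot",
                 labels: np.ndarray | None = None) -> SBMNOutput:
    """Run all k class modules on the batch.

    ``labels`` (ground truth) select which class module's mod_x / remake_x
    represent each sample during training; without labels the predicted
    class (argmax of the stacked scores) is used instead.
    """
    x = as_tensor(x)
    k = memory.k
    if len(all_params) != k:
        raise ValidationError(
            f"memory has k={k} classes but {len(all_params)} module params given")
    mod_x_pc, mod_m, score_cols, remake_pc, head_bundles = [], [], [], [], []
    for t in range(k):
        mod_x_t, mod_m_t, sim_bar_t, remake_t, bundles = run_basic_module(
            x, memory.class_slice(t), all_params[t], similarity_fn)
        mod_x_pc.append(mod_x_t)
        mod_m.append(mod_m_t)
        remake_pc.append(remake_t)
        head_bundles.append(bundles)
        score_cols.append(ad.reshape(sim_bar_t, (-1, 1)))
    class_scores = ad.concat(score_cols, axis=1)             # (B, k)
    if labels is not None:
        choice = np.asarray(labels, dtype=int)
        if choice.shape[0] != x.shape[0]:
            raise ValidationError("labels length must match batch size")
    else:
        choice = np.argmax(class_scores.value, axis=1)
    mod_x = _select_rows(mod_x_pc, choice, k)
    remake_x = _select_rows(remake_pc, choice, k)
    return SBMNOutput(mod_x=mod_x, mod_m=mod_m, class_scores=class_scores,
                      remake_x=remake_x, mod_x_per_class=mod_x_pc,
                      remake_per_class=remake_pc, head_bundles=head_bundles)


def encoded_keys(x, m_t, params: BasicModuleParams):
    """Concatenated per-head key projections, for channel-level analysis.

    Returns ``(x_K, hid_K)``: x_K stacks the four heads' feature keys into a
    length-H vector per sample; hid_K stacks the slot-averaged memory keys.
    """
    x, m_t = as_tensor(x), as_tensor(m_t)
    xs, ms = [], []
    for head in params.heads:
        K_x, K_m, _, _ = encode(x, m_t, head)
        xs.append(K_x.value)
        ms.append(K_m.value.mean(axis=0))
    return np.concatenate(xs, axis=1), np.concatenate(ms)
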