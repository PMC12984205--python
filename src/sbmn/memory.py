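"""Category memory: the network's persistent per-class feature bank.

The bank holds M slots of H-dimensional feature-like vectors for each of the
k classes.  During training the whole bank is *replaced* after every
optimizer step by the modified memory the similarity module produced for
that step (gradient-decoupled at commit time); at test time the bank is
frozen and every write is rejected.  The bank is also the subject of the
memory-manipulation experiments: zeroing, single-class copying, random
re-initialization and class swapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import StateError, ValidationError

MANIPULATION_MODES = ("zeros", "single_class", "random", "swap")


@dataclass
class CategoryMemory:
    """External memory bank of shape (M, k, H) plus an update counter."""

    bank: np.ndarray  # (M, k, H)
    step: int = 0
    frozen: bool = False

    def __post_init__(self):
        self.bank = np.asarray(self.bank, dtype=np.float64)
        if self.bank.ndim != 3:
            raise ValidationError("memory bank must be a (M, k, H) array")
        if not np.all(np.isfinite(self.bank)):
            raise ValidationError("memory bank contains non-finite entries")

    @property
    def M(self) -> int:
        return self.bank.shape[0]

    @property
    def k(self) -> int:
        return self.bank.shape[1]

    @property
    def H(self) -> int:
        return self.bank.shape[2]

    def class_slice(self, t: int) -> np.ndarray:
        """The (M, H) memory set of class ``t``."""
        if not 0 <= t < self.k:
            raise ValidationError(f"class index {t} outside 0..{self.k - 1}")
        return self.bank[:, t, :]

    def slices(self) -> list[np.ndarray]:
        return [self.class_slice(t) for t in range(self.k)]

    def freeze(self) -> None:
        self.frozen = True

    def unfreeze(self) -> None:
        self.frozen = False

    def copy(self) -> "CategoryMemory":
        return CategoryMemory(self.bank.copy(), self.step, self.frozen)


def init_memory(M: int, k: int, H: int, seed: int) -> CategoryMemory:
    """Random bank with entries of mean 0 and variance 1, seeded."""
    if M < 1 or k < 1 or H < 1:
        raise ValidationError(f"memory dims must be positive, got M={M}, k={k}, H={H}")
    rng = np.random.default_rng(seed)
    return CategoryMemory(rng.standard_normal((M, k, H)))


def commit_update(memory: CategoryMemory,
                  new_slices: list[np.ndarray]) -> CategoryMemory:
    """Replace every class slice with the step's modified memory.

    Pure replacement: no blending with, or residue of, the previous bank.
    The incoming slices are copied so the stored state is decoupled from any
    autodiff graph that produced them.
    """
    if memory.frozen:
        raise StateError("cannot commit to a frozen memory bank (test mode)")
    if len(new_slices) != memory.k:
        raise ValidationError(
            f"expected {memory.k} class slices, got {len(new_slices)}")
    bank = np.empty_like(memory.bank)
    for t, s in enumerate(new_slices):
        s = np.asarray(s, dtype=np.float64)
        if s.shape != (memory.M, memory.H):
            raise ValidationError(
                f"slice {t} has shape {s.shape}, expected {(memory.M, memory.H)}")
        bank[:, t, :] = s
    return CategoryMemory(bank, step=memory.step + 1, frozen=False)


def blend_update(memory: CategoryMemory, new_slices: list[np.ndarray],
                 alpha: float = 1.0) -> CategoryMemory:
    """Exponential-blend variant: bank <- alpha * new + (1 - alpha) * old.

    ``alpha=1`` recovers the default full-replacement rule."""
    replaced = commit_update(memory, new_slices)
    if alpha != 1.0:
        replaced.bank = alpha * replaced.bank + (1.0 - alpha) * memory.bank
    return replaced


def manipulate(memory: CategoryMemory, mode: str,
               source_class: int | None = None,
               seed: int | None = None) -> CategoryMemory:
    """Return a manipulated copy of the bank (the input is never mutated).

    zeros         -- every entry set to 0
    single_class  -- every class slice replaced by ``source_class``'s slice
    random        -- re-drawn from the N(0, 1) initialization distribution
    swap          -- class slices exchanged (k = 2)
    """
    if mode not in MANIPULATION_MODES:
        raise ValidationError(
            f"unknown manipulation mode {mode!r}; choose from {MANIPULATION_MODES}")
    bank = memory.bank.copy()
    if mode == "zeros":
        bank[:] = 0.0
    elif mode == "single_class":
        if source_class is None or not 0 <= source_class < memory.k:
            raise ValidationError("single_class mode needs a valid source_class")
        src = bank[:, source_class, :].copy()
        for t in range(memory.k):
            bank[:, t, :] = src
    elif mode == "random":
        if seed is None:
            raise ValidationError("random mode needs a seed")
        bank = np.random.default_rng(seed).standard_normal(bank.shape)
    elif mode == "swap":
        if memory.k < 2:
            raise ValidationError("swap requires at least 2 classes")
        if memory.k != 2:
            raise ValidationError("swap is defined for exactly 2 classes")
        bank = bank[:, ::-1, :].copy()
    return CategoryMemory(bank, step=memory.step, frozen=memory.frozen)


def save_memory(memory: CategoryMemory, path: str | Path) -> None:
    np.savez(path, bank=memory.bank, step=np.array(memory.step),
             frozen=np.array(int(memory.frozen)))


def load_memory(path: str | Path) -> CategoryMemory:
    with np.load(path) as data:
        return CategoryMemory(data["bank"], int(data["step"]),
                              bool(int(data["frozen"])))
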