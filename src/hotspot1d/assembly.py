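"""Dataset assembly: splits, interval subsampling, SMOTE, class weights.

The benchmark corpus is severely imbalanced (349 hotspots vs 22244
non-hotspots, about 1:63).  Construction proceeds in three moves:

1. stride-63 interval subsampling of the ordered negative pool gives
   deterministic, pairwise-disjoint negative subsets of 349 each;
2. the first subset joins the positives to form a balanced base corpus,
   which is split 1/5 test, then 1/5 of the remainder validation;
3. the training partition is expanded with four further negative subsets
   and SMOTE-synthesized positives until the two classes balance exactly
   (232 + 1378 positives vs 214 + 4*349 negatives = 1610 each, 3220 total).

SMOTE synthesizes a minority point as X_old + r * (X_n - X_old) with X_n one
of X_old's k nearest minority neighbors and r uniform on (0, 1); class
weighting (w_c = N / (2 N_c)) is the in-loss alternative to oversampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, TypeVar

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .windowing import WindowDataset

__all__ = [
    "SplitSpec",
    "IntervalSamplerSpec",
    "SmoteSpec",
    "split_dataset",
    "interval_subsample",
    "smote_generate",
    "compute_class_weights",
    "assemble_training_set",
]

T = TypeVar("T")


@dataclass(frozen=True)
class SplitSpec:
    """1/5 of the corpus becomes the test set; 1/5 of what remains becomes
    the validation set.  Partition sizes round half away from zero."""

    test_fraction: float = 0.2
    val_fraction_of_remainder: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name, frac in (
            ("test_fraction", self.test_fraction),
            ("val_fraction_of_remainder", self.val_fraction_of_remainder),
        ):
            if not 0.0 < frac < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {frac}")


@dataclass(frozen=True)
class IntervalSamplerSpec:
    """Stride sampling of the ordered negative pool: ``n_subsets`` strided
    subsets at offsets ``first_offset`` .. ``first_offset + n_subsets - 1``,
    each truncated to ``subset_size``.  Distinct offsets below the interval
    give pairwise-disjoint subsets, so a base subset at offset 0 and
    expansion subsets starting at offset 1 never overlap."""

    interval: int = 63
    n_subsets: int = 1
    subset_size: int | None = None
    first_offset: int = 0

    def __post_init__(self) -> None:
        if self.interval < 1:
            raise ValueError("interval must be positive")
        if self.first_offset < 0:
            raise ValueError("first_offset must be nonnegative")
        if not 1 <= self.n_subsets or self.first_offset + self.n_subsets > self.interval:
            raise ValueError("offsets first_offset..first_offset+n_subsets-1 must stay below interval")


@dataclass(frozen=True)
class SmoteSpec:
    """k-nearest-neighbor interpolation parameters for minority synthesis."""

    k: int = 5
    n_new: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be positive")
        if self.n_new < 0:
            raise ValueError("n_new must be nonnegative")


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def split_dataset(
    examples: WindowDataset, spec: SplitSpec, stratify: bool = False
) -> tuple[WindowDataset, WindowDataset, WindowDataset]:
    """Random disjoint (train, validation, test) partition.

    |test| = round(N * test_fraction), |validation| = round((N - |test|) *
    val_fraction_of_remainder); selection is uniform under the seed.  With
    N=698 and the default fifths this yields 140 test and 112 validation
    examples.  Unstratified by default; ``stratify=True`` draws each class
    proportionally.
    """
    n = len(examples)
    if n < 3:
        raise ValueError("need at least 3 examples to split")
    rng = np.random.default_rng(spec.seed)

    def sizes(m: int) -> tuple[int, int]:
        n_test = _round_half_away(m * spec.test_fraction)
        n_val = _round_half_away((m - n_test) * spec.val_fraction_of_remainder)
        return n_test, n_val

    if stratify:
        test_idx: list[np.ndarray] = []
        val_idx: list[np.ndarray] = []
        train_idx: list[np.ndarray] = []
        for cls in (0, 1):
            cls_idx = np.flatnonzero(examples.y == cls)
            perm = rng.permutation(cls_idx)
            n_test, n_val = sizes(len(perm))
            test_idx.append(perm[:n_test])
            val_idx.append(perm[n_test : n_test + n_val])
            train_idx.append(perm[n_test + n_val :])
        parts = tuple(np.sort(np.concatenate(p)) for p in (train_idx, val_idx, test_idx))
    else:
        perm = rng.permutation(n)
        n_test, n_val = sizes(n)
        parts = (
            np.sort(perm[n_test + n_val :]),
            np.sort(perm[n_test : n_test + n_val]),
            np.sort(perm[:n_test]),
        )
    train, val, test = (examples.subset(p) for p in parts)
    return train, val, test


def interval_subsample(
    items: Sequence[T], interval: int, offset: int = 0, subset_size: int | None = None
) -> list[T]:
    """Every ``interval``-th item starting at ``offset``, optionally truncated
    to the first ``subset_size`` hits.

    Items must arrive in a fixed documented order — (protein_id, position)
    for residue pools — so the draw is reproducible without randomness.
    Distinct offsets below the interval give pairwise-disjoint subsets.
    """
    if not 0 <= offset < interval:
        raise ValueError(f"offset must satisfy 0 <= offset < interval, got {offset}")
    subset = list(items[offset::interval])
    if subset_size is not None:
        if subset_size > len(subset):
            raise ValueError(
                f"requested subset_size {subset_size} but stride yields only {len(subset)}"
            )
        subset = subset[:subset_size]
    return subset


def smote_generate(
    minority: np.ndarray, spec: SmoteSpec, r_override: float | None = None
) -> np.ndarray:
    """Synthesize ``spec.n_new`` minority rows by k-NN interpolation.

    Each synthetic row is X_old + r * (X_n - X_old): X_old a uniformly chosen
    minority row, X_n uniform over X_old's k nearest minority neighbors under
    Euclidean distance (self excluded), r uniform on the open interval (0, 1).
    ``r_override`` pins r for testing (0 reproduces X_old, 1 reproduces X_n).
    Deterministic under ``spec.seed``.
    """
    minority = np.asarray(minority, dtype=np.float64)
    if minority.ndim != 2:
        raise ValueError("minority must be a 2-D matrix")
    m = len(minority)
    if m <= spec.k:
        raise ValueError(f"need more than k={spec.k} minority samples, got {m}")
    if spec.n_new == 0:
        return np.zeros((0, minority.shape[1]), dtype=minority.dtype)

    nn = NearestNeighbors(n_neighbors=spec.k + 1).fit(minority)
    # first neighbor is the point itself; keep the k genuine neighbors
    neighbor_idx = nn.kneighbors(minority, return_distance=False)[:, 1:]

    rng = np.random.default_rng(spec.seed)
    old_idx = rng.integers(0, m, size=spec.n_new)
    pick = rng.integers(0, spec.k, size=spec.n_new)
    if r_override is not None:
        r = np.full(spec.n_new, float(r_override))
    else:
        r = rng.uniform(0.0, 1.0, size=spec.n_new)
        r[r == 0.0] = 0.5  # open interval: measure-zero guard
    x_old = minority[old_idx]
    x_n = minority[neighbor_idx[old_idx, pick]]
    return x_old + r[:, None] * (x_n - x_old)


def compute_class_weights(y: np.ndarray) -> dict[int, float]:
    """Balanced inverse-frequency weights w_c = N / (2 N_c).

    The minority class gets weight >= 1, the majority <= 1, and the weighted
    class totals are equal — the in-loss alternative to SMOTE oversampling.
    """
    y = np.asarray(y)
    n = len(y)
    n_pos = int((y == 1).sum())
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute class weights")
    return {0: n / (2.0 * n_neg), 1: n / (2.0 * n_pos)}


def assemble_training_set(
    train_pos: WindowDataset,
    train_neg: WindowDataset,
    extra_neg_pool: WindowDataset,
    sampler: IntervalSamplerSpec,
    smote: SmoteSpec,
    seed: int = 0,
    forbid_meta: set[tuple[str, int]] | None = None,
) -> WindowDataset:
    """Build the balanced, expanded training set.

    Negatives are the split's own training negatives plus ``sampler.n_subsets``
    interval subsets of the (ordered, split-exclusive) extra negative pool;
    positives are the training positives plus exactly enough SMOTE-synthetic
    examples to balance.  With the benchmark composition — 232 positives,
    214 negatives, 4 extra subsets of 349 — this makes 1378 synthetic
    positives and 3220 examples in all.  ``forbid_meta`` (validation/test
    keys) triggers a leakage error if any pool member belongs to it.  Output
    order is shuffled under ``seed``.
    """
    # pool arrives pre-ordered by (protein_id, position); the stride is over indices
    extras = [
        extra_neg_pool.subset(
            interval_subsample(
                list(range(len(extra_neg_pool))),
                sampler.interval,
                offset,
                sampler.subset_size,
            )
        )
        for offset in range(sampler.first_offset, sampler.first_offset + sampler.n_subsets)
    ]
    negatives = WindowDataset.concatenate([train_neg, *extras]) if extras else train_neg
    if forbid_meta:
        leaked = [m for m in negatives.meta + train_pos.meta if m in forbid_meta]
        if leaked:
            raise ValueError(f"leakage: {len(leaked)} training examples shared with held-out splits")
    if not np.all(negatives.y == 0):
        raise ValueError("negative inputs contain positive labels")
    if not np.all(train_pos.y == 1):
        raise ValueError("train_pos contains negative labels")

    n_new = len(negatives) - len(train_pos)
    if n_new < 0:
        raise ValueError(
            f"{len(train_pos)} positives already exceed {len(negatives)} negatives; "
            "SMOTE cannot remove samples"
        )
    parts = [train_pos, negatives]
    if n_new > 0:
        w, d = train_pos.width, train_pos.dim
        flat = train_pos.X.reshape(len(train_pos), w * d)
        synthetic = smote_generate(
            flat, SmoteSpec(k=smote.k, n_new=n_new, seed=smote.seed)
        )
        parts.append(
            WindowDataset(
                X=synthetic.reshape(n_new, w, d).astype(np.float32),
                y=np.ones(n_new, dtype=np.int8),
                meta=[("synthetic:smote", i + 1) for i in range(n_new)],
            )
        )
    combined = WindowDataset.concatenate(parts)
    order = np.random.default_rng(seed).permutation(len(combined))
    return combined.subset(order)
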