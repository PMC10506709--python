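"""End-to-end orchestration: corpus -> windows -> splits -> balanced training.

This mirrors the benchmark construction recipe at any corpus size:

1. window every labeled residue;
2. take the offset-0 interval subset of the ordered negatives, sized to the
   positive count, to form a balanced base corpus;
3. split the base corpus into train / validation / test fifths;
4. expand the training partition with further interval subsets of the
   negative pool (offsets 1..n, disjoint from the base subset by
   construction) and balance by SMOTE synthesis or by class weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .assembly import (
    IntervalSamplerSpec,
    SmoteSpec,
    SplitSpec,
    assemble_training_set,
    compute_class_weights,
    interval_subsample,
    split_dataset,
)
from .datamodel import HotspotDataset
from .embedders import ResidueFeatureMatrix
from .windowing import WindowConfig, WindowDataset, build_window_dataset

__all__ = ["PreparedData", "prepare"]


@dataclass
class PreparedData:
    """Everything a training run needs, plus the split manifest keys."""

    train: WindowDataset  # balanced/expanded training set
    validation: WindowDataset
    test: WindowDataset
    class_weights: dict[int, float] | None  # set in class_weight mode
    partitions: dict[str, list[tuple[str, int]]] = field(default_factory=dict)


def prepare(
    ds: HotspotDataset,
    provider: Callable[..., ResidueFeatureMatrix],
    window_cfg: WindowConfig,
    split_spec: SplitSpec,
    n_extra_subsets: int = 4,
    smote_k: int = 5,
    balancing: str = "smote",
    stratify: bool = False,
) -> PreparedData:
    """Run the full assembly recipe on a labeled corpus.

    The stride interval is the corpus imbalance floor (negatives // positives),
    so the base subset always matches the positive count; ``n_extra_subsets``
    further subsets (default 4, as in the benchmark recipe) expand the
    training negatives.  ``balancing`` is ``"smote"`` (synthesize positives
    until balanced) or ``"class_weight"`` (keep counts, return loss weights).
    """
    if balancing not in ("smote", "class_weight"):
        raise ValueError("balancing must be 'smote' or 'class_weight'")
    windows = build_window_dataset(ds, provider, window_cfg)
    n_pos, n_neg = windows.class_counts()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("corpus must contain both classes")
    interval = max(n_neg // n_pos, 1)
    if n_extra_subsets + 1 > interval:
        raise ValueError(
            f"imbalance floor {interval} supports at most {interval - 1} extra subsets"
        )

    pos_idx = np.flatnonzero(windows.y == 1)
    neg_idx = np.flatnonzero(windows.y == 0)  # already (protein_id, position)-ordered
    base_neg = interval_subsample(list(neg_idx), interval, offset=0, subset_size=n_pos)
    base = windows.subset(np.sort(np.concatenate([pos_idx, base_neg])))

    train_raw, validation, test = split_dataset(base, split_spec, stratify=stratify)
    train_pos = train_raw.subset(np.flatnonzero(train_raw.y == 1))
    train_neg = train_raw.subset(np.flatnonzero(train_raw.y == 0))
    neg_pool = windows.subset(neg_idx)
    sampler = IntervalSamplerSpec(
        interval=interval,
        n_subsets=n_extra_subsets,
        subset_size=n_pos,
        first_offset=1,
    )
    held_out = set(validation.meta) | set(test.meta)

    if balancing == "smote":
        train = assemble_training_set(
            train_pos,
            train_neg,
            neg_pool,
            sampler,
            SmoteSpec(k=smote_k, seed=split_spec.seed),
            seed=split_spec.seed,
            forbid_meta=held_out,
        )
        class_weights = None
    else:
        extras = [
            neg_pool.subset(
                interval_subsample(list(range(len(neg_pool))), interval, off, n_pos)
            )
            for off in range(1, 1 + n_extra_subsets)
        ]
        train = WindowDataset.concatenate([train_raw, *extras])
        leaked = set(train.meta) & held_out
        if leaked:
            raise ValueError(f"leakage: {len(leaked)} training examples shared with held-out splits")
        order = np.random.default_rng(split_spec.seed).permutation(len(train))
        train = train.subset(order)
        class_weights = compute_class_weights(train.y)

    partitions = {
        "train": list(train_raw.meta),
        "validation": list(validation.meta),
        "test": list(test.meta),
    }
    return PreparedData(
        train=train,
        validation=validation,
        test=test,
        class_weights=class_weights,
        partitions=partitions,
    )
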