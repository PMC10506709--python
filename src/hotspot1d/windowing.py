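"""Zero-padded sliding windows over per-residue feature matrices.

A window of odd width w centered on residue i holds feature rows
i-(w-1)/2 .. i+(w-1)/2; positions falling outside the sequence are all-zero
rows (zero padding, not edge replication — a padded row is distinct from any
real residue's one-hot row).  Every example therefore has the same w x D
shape regardless of where in the protein its center lies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .datamodel import HOTSPOT, DDG_THRESHOLD, HotspotDataset
from .embedders import ResidueFeatureMatrix

__all__ = ["WindowConfig", "WindowDataset", "extract_window", "build_window_dataset", "dense_windows"]

#: Window widths explored in the width sweep (odd, 21..41); 33 is the default.
VALID_WIDTHS = tuple(range(21, 42, 2))


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window geometry.

    width must be odd; widths outside 21..41 are rejected unless
    ``allow_any_width`` (the sweep range studied for this task)."""

    width: int = 33
    allow_any_width: bool = False

    def __post_init__(self) -> None:
        if self.width < 1 or self.width % 2 == 0:
            raise ValueError(f"window width must be a positive odd integer, got {self.width}")
        if not self.allow_any_width and self.width not in VALID_WIDTHS:
            raise ValueError(
                f"width {self.width} outside the validated range {VALID_WIDTHS[0]}..)"
                f"{VALID_WIDTHS[-1]}; pass allow_any_width=True to relax"
            )

    @property
    def flank(self) -> int:
        return (self.width - 1) // 2


@dataclass
class WindowDataset:
    """N window examples: X is (N, w, D), y is binary (1 = hotspot), meta
    holds the (protein_id, 1-based position) key of each example."""

    X: np.ndarray
    y: np.ndarray
    meta: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float32)
        self.y = np.asarray(self.y, dtype=np.int8)
        if self.X.ndim != 3:
            raise ValueError(f"X must be (N, w, D), got shape {self.X.shape}")
        if len(self.y) != len(self.X) or len(self.meta) != len(self.X):
            raise ValueError("X, y and meta lengths differ")
        if len(self.y) and not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return len(self.X)

    @property
    def width(self) -> int:
        return self.X.shape[1]

    @property
    def dim(self) -> int:
        return self.X.shape[2]

    def class_counts(self) -> tuple[int, int]:
        """(n_positive, n_negative)."""
        n_pos = int(self.y.sum())
        return n_pos, len(self.y) - n_pos

    def subset(self, indices: np.ndarray | list[int]) -> "WindowDataset":
        indices = np.asarray(indices, dtype=np.intp)
        return WindowDataset(
            X=self.X[indices], y=self.y[indices], meta=[self.meta[i] for i in indices]
        )

    @staticmethod
    def concatenate(parts: list["WindowDataset"]) -> "WindowDataset":
        parts = [p for p in parts if len(p)]
        if not parts:
            raise ValueError("nothing to concatenate")
        return WindowDataset(
            X=np.concatenate([p.X for p in parts]),
            y=np.concatenate([p.y for p in parts]),
            meta=[m for p in parts for m in p.meta],
        )

    def save(self, path: str | Path) -> None:
        pids = np.array([m[0] for m in self.meta])
        positions = np.array([m[1] for m in self.meta], dtype=np.int64)
        np.savez_compressed(path, X=self.X, y=self.y, protein_ids=pids, positions=positions)

    @staticmethod
    def load(path: str | Path) -> "WindowDataset":
        with np.load(path, allow_pickle=False) as npz:
            meta = list(zip((str(p) for p in npz["protein_ids"]), (int(p) for p in npz["positions"])))
            return WindowDataset(X=npz["X"], y=npz["y"], meta=meta)


def extract_window(
    features: ResidueFeatureMatrix | np.ndarray, center: int, cfg: WindowConfig
) -> np.ndarray:
    """The w x D window centered on 0-based residue ``center``.

    Out-of-range rows are all zeros; the center residue always sits at row
    index ``cfg.flank``.
    """
    values = features.values if isinstance(features, ResidueFeatureMatrix) else features
    L, D = values.shape
    if not 0 <= center < L:
        raise IndexError(f"center {center} out of range for length {L}")
    window = np.zeros((cfg.width, D), dtype=values.dtype)
    lo = center - cfg.flank
    hi = center + cfg.flank + 1
    src_lo, src_hi = max(lo, 0), min(hi, L)
    window[src_lo - lo : src_hi - lo] = values[src_lo:src_hi]
    return window


def build_window_dataset(
    ds: HotspotDataset,
    provider: Callable[..., ResidueFeatureMatrix],
    cfg: WindowConfig,
    threshold: float = DDG_THRESHOLD,
) -> WindowDataset:
    """One window example per labeled annotation (unknown labels skipped).

    ``provider`` maps a ProteinRecord to its feature matrix (an embedder or a
    cache lookup).  Example order is deterministic — sorted by (protein_id,
    position) — so downstream splits are reproducible.  Feature matrices
    whose row count disagrees with the sequence length, or proteins with no
    matrix at all, raise listing the offending ids.
    """
    labeled = [a for a in ds.annotations if a.effective_label(threshold) is not None]
    labeled.sort(key=lambda a: (a.protein_id, a.position))
    needed = sorted({a.protein_id for a in labeled})

    matrices: dict[str, ResidueFeatureMatrix] = {}
    missing: list[str] = []
    for pid in needed:
        prot = ds.proteins.get(pid)
        if prot is None:
            missing.append(pid)
            continue
        try:
            mat = provider(prot)
        except KeyError:
            missing.append(pid)
            continue
        if mat.length != prot.length:
            raise ValueError(
                f"{pid}: feature matrix rows {mat.length} != sequence length {prot.length}"
            )
        matrices[pid] = mat
    if missing:
        raise ValueError(f"no feature matrix for proteins: {', '.join(missing)}")

    dims = {m.dim for m in matrices.values()}
    if len(dims) > 1:
        raise ValueError(f"inconsistent embedding dims across proteins: {sorted(dims)}")

    if not labeled:
        dim = dims.pop() if dims else 0
        return WindowDataset(
            X=np.zeros((0, cfg.width, dim), dtype=np.float32), y=np.zeros(0), meta=[]
        )
    X = np.stack(
        [extract_window(matrices[a.protein_id], a.position - 1, cfg) for a in labeled]
    )
    y = np.array(
        [1 if a.effective_label(threshold) == HOTSPOT else 0 for a in labeled], dtype=np.int8
    )
    meta = [(a.protein_id, a.position) for a in labeled]
    return WindowDataset(X=X, y=y, meta=meta)


def dense_windows(features: ResidueFeatureMatrix, cfg: WindowConfig) -> np.ndarray:
    """All L windows of a protein (one per residue), for whole-sequence
    prediction.  Shape (L, w, D)."""
    return np.stack([extract_window(features, i, cfg) for i in range(features.length)])
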