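"""Per-residue feature matrices: one-hot encoding and precomputed embeddings.

Each embedder maps a protein of length L to an L x D real matrix, one row per
residue.  One-hot (D=21) is built in; learned embeddings from pretrained
sequence models (e.g. a biLSTM language model yielding D=4096 per residue)
enter as precomputed matrices keyed by protein id.  Concatenating a 4096-dim
learned embedding with the 21-dim one-hot gives the 4117-dim representation
used by the full pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .datamodel import ALPHABET, ProteinRecord

__all__ = [
    "ResidueFeatureMatrix",
    "EmbedderSpec",
    "one_hot_embed",
    "load_precomputed",
    "concat_embed",
    "OneHotEmbedder",
    "PrecomputedEmbedder",
    "save_precomputed",
]

#: Fixed one-hot column order: the 20 standard residues alphabetically, 'X' last.
AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}


@dataclass(frozen=True)
class EmbedderSpec:
    """Name and per-residue dimensionality of an embedding scheme."""

    name: str
    dim: int

    def __post_init__(self) -> None:
        if self.dim <= 0:
            raise ValueError("embedding dim must be positive")


@dataclass(frozen=True)
class ResidueFeatureMatrix:
    """An L x D matrix of per-residue features for one protein."""

    protein_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError(
                f"{self.protein_id}: feature matrix must be 2-D, got {self.values.ndim}-D"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.protein_id}: non-finite feature values")

    @property
    def length(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


def one_hot_embed(protein: ProteinRecord) -> ResidueFeatureMatrix:
    """21-dim indicator encoding: one column per alphabet symbol, column
    order A..Y then 'X' (documented in :data:`AA_INDEX`)."""
    idx = np.fromiter((AA_INDEX[c] for c in protein.sequence), dtype=np.intp)
    mat = np.zeros((protein.length, len(ALPHABET)), dtype=np.float32)
    mat[np.arange(protein.length), idx] = 1.0
    return ResidueFeatureMatrix(protein_id=protein.id, values=mat)


def load_precomputed(
    path: str | Path, protein_id: str, expected_length: int | None = None
) -> ResidueFeatureMatrix:
    """Fetch the precomputed L x D matrix for ``protein_id``.

    The container is an HDF5 file with one dataset per protein id; a plain
    whitespace-delimited text matrix (one file per protein, L rows x D
    columns) is accepted as a fallback dialect.  Row count is validated
    against ``expected_length`` when given.
    """
    path = Path(path)
    if h5py.is_hdf5(path):
        with h5py.File(path, "r") as fh:
            if protein_id not in fh:
                raise KeyError(f"{path}: no embedding stored for protein {protein_id!r}")
            values = np.asarray(fh[protein_id], dtype=np.float32)
    else:
        values = np.atleast_2d(np.loadtxt(path, dtype=np.float32))
    if expected_length is not None and values.shape[0] != expected_length:
        raise ValueError(
            f"{protein_id}: stored matrix has {values.shape[0]} rows but the "
            f"sequence has {expected_length} residues"
        )
    return ResidueFeatureMatrix(protein_id=protein_id, values=values)


def save_precomputed(path: str | Path, matrices: dict[str, np.ndarray]) -> None:
    """Write a keyed HDF5 container (protein id -> L x D float32 matrix)."""
    with h5py.File(path, "w") as fh:
        for pid, mat in matrices.items():
            fh.create_dataset(pid, data=np.asarray(mat, dtype=np.float32))


def concat_embed(a: ResidueFeatureMatrix, b: ResidueFeatureMatrix) -> ResidueFeatureMatrix:
    """Row-wise concatenation: row i of the result is row i of ``a`` followed
    by row i of ``b`` (dim Da + Db).  E.g. 4096-dim learned + 21-dim one-hot
    -> 4117-dim."""
    if a.protein_id != b.protein_id:
        raise ValueError(f"protein id mismatch: {a.protein_id!r} vs {b.protein_id!r}")
    if a.length != b.length:
        raise ValueError(
            f"{a.protein_id}: row-count mismatch {a.length} vs {b.length}"
        )
    return ResidueFeatureMatrix(
        protein_id=a.protein_id, values=np.hstack([a.values, b.values])
    )


class OneHotEmbedder:
    """Callable provider: protein -> 21-dim one-hot matrix."""

    spec = EmbedderSpec(name="one_hot", dim=len(ALPHABET))

    def __call__(self, protein: ProteinRecord) -> ResidueFeatureMatrix:
        return one_hot_embed(protein)


class PrecomputedEmbedder:
    """Provider backed by a keyed matrix container, optionally concatenating
    the one-hot encoding to each stored matrix (the 4096 + 21 = 4117 scheme)."""

    def __init__(self, path: str | Path, dim: int, append_one_hot: bool = False):
        self.path = Path(path)
        self.append_one_hot = append_one_hot
        total = dim + (len(ALPHABET) if append_one_hot else 0)
        name = f"precomputed{dim}" + ("+one_hot" if append_one_hot else "")
        self.spec = EmbedderSpec(name=name, dim=total)

    def __call__(self, protein: ProteinRecord) -> ResidueFeatureMatrix:
        mat = load_precomputed(self.path, protein.id, expected_length=protein.length)
        if self.append_one_hot:
            mat = concat_embed(mat, one_hot_embed(protein))
        return mat
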