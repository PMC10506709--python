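"""Readers and writers: FASTA sequences, residue-annotation TSV, split manifests.

Positions are 1-based in every file (matching residue numbering conventions);
conversion to 0-based indices happens exactly once, at this boundary's callers.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .datamodel import (
    HotspotDataset,
    ProteinRecord,
    ResidueAnnotation,
    normalize_sequence,
)

__all__ = [
    "AnnotationParseError",
    "read_fasta",
    "write_fasta",
    "read_annotations",
    "write_annotations",
    "read_dataset",
    "write_split_manifest",
    "read_split_manifest",
]

ANNOTATION_COLUMNS = ("protein_id", "position", "wild_type", "ddg", "label")


class AnnotationParseError(ValueError):
    """Raised for malformed annotation tables, naming the offending line."""


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Parse a FASTA file into normalized :class:`ProteinRecord` objects.

    Lowercase letters are uppercased and non-standard letters mapped to 'X'.
    The header token up to the first whitespace becomes the id.  An empty
    file yields an empty list with a warning; sequence data before the first
    header is a parse error naming the line.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise AnnotationParseError(
                    f"{path}:{lineno}: sequence data before the first FASTA header"
                )
            break
        else:
            warnings.warn(f"{path}: empty FASTA file", stacklevel=2)
            return []
    records = [
        ProteinRecord(id=rec.id, sequence=normalize_sequence(str(rec.seq)))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    return records


def write_fasta(path: str | Path, proteins: Iterable[ProteinRecord], width: int = 60) -> None:
    with open(path, "w") as fh:
        for prot in proteins:
            fh.write(f">{prot.id}\n")
            for i in range(0, prot.length, width):
                fh.write(prot.sequence[i : i + width] + "\n")


def _parse_row(path: Path, lineno: int, fields: list[str]) -> ResidueAnnotation:
    if len(fields) != len(ANNOTATION_COLUMNS):
        raise AnnotationParseError(
            f"{path}:{lineno}: expected {len(ANNOTATION_COLUMNS)} columns, got {len(fields)}"
        )
    protein_id, pos_s, wt, ddg_s, label_s = (f.strip() for f in fields)
    try:
        position = int(pos_s)
    except ValueError:
        raise AnnotationParseError(f"{path}:{lineno}: non-integer position {pos_s!r}") from None
    if not ddg_s and not label_s:
        raise AnnotationParseError(f"{path}:{lineno}: row has neither ddg nor label")
    ddg = float(ddg_s) if ddg_s else None
    try:
        return ResidueAnnotation(
            protein_id=protein_id,
            position=position,
            wild_type=wt or None,
            ddg=ddg,
            label=label_s or None,
        )
    except ValueError as exc:
        raise AnnotationParseError(f"{path}:{lineno}: {exc}") from None


def read_annotations(path: str | Path) -> list[ResidueAnnotation]:
    """Read a tab-separated residue annotation table.

    Expected header: ``protein_id  position  wild_type  ddg  label`` with the
    empty string for absent values; each row must carry a ddG, a label, or both.
    """
    path = Path(path)
    annotations: list[ResidueAnnotation] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(h.strip() for h in header) != ANNOTATION_COLUMNS:
            raise AnnotationParseError(
                f"{path}:1: header must be {' '.join(ANNOTATION_COLUMNS)}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            annotations.append(_parse_row(path, lineno, line.rstrip("\n").split("\t")))
    return annotations


def write_annotations(path: str | Path, annotations: Iterable[ResidueAnnotation]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for ann in annotations:
            ddg = "" if ann.ddg is None else repr(ann.ddg)
            fh.write(
                f"{ann.protein_id}\t{ann.position}\t{ann.wild_type or ''}\t"
                f"{ddg}\t{ann.label or ''}\n"
            )


def read_dataset(
    fasta_path: str | Path,
    annotation_path: str | Path,
    wild_type_mismatch: str = "error",
) -> HotspotDataset:
    """Load sequences + annotations and validate cross-references."""
    proteins = {p.id: p for p in read_fasta(fasta_path)}
    ds = HotspotDataset(proteins=proteins, annotations=read_annotations(annotation_path))
    for msg in ds.validate(wild_type_mismatch=wild_type_mismatch):
        warnings.warn(msg, stacklevel=2)
    return ds


def write_split_manifest(
    path: str | Path,
    seed: int,
    partitions: dict[str, list[tuple[str, int]]],
) -> None:
    """Record a train/validation/test split as TSV so a run is exactly
    reconstructable.  ``partitions`` maps partition name to (protein_id,
    1-based position) keys; the seed goes in the header comment."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# seed: {seed}\n")
        fh.write("protein_id\tposition\tpartition\n")
        for name, keys in partitions.items():
            for pid, pos in keys:
                fh.write(f"{pid}\t{pos}\t{name}\n")


def read_split_manifest(path: str | Path) -> tuple[int, dict[str, list[tuple[str, int]]]]:
    partitions: dict[str, list[tuple[str, int]]] = {}
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().strip()
        if not first.startswith("# seed:"):
            raise AnnotationParseError(f"{path}:1: missing '# seed:' header")
        seed = int(first.split(":", 1)[1])
        fh.readline()  # column header
        for line in fh:
            if not line.strip():
                continue
            pid, pos, name = line.rstrip("\n").split("\t")
            partitions.setdefault(name, []).append((pid, int(pos)))
    return seed, partitions
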