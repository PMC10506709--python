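"""Core domain types for hot-spot residue datasets.

A *hot spot* is an interface residue whose mutation to alanine raises the
binding free energy by more than 2 kcal/mol (ddG > 2).  Datasets pair protein
sequences with per-residue annotations carrying either a measured ddG, a
binary hotspot label, or both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "ALPHABET",
    "STANDARD_AA",
    "UNKNOWN_AA",
    "HOTSPOT",
    "NON_HOTSPOT",
    "DDG_THRESHOLD",
    "ProteinRecord",
    "ResidueAnnotation",
    "HotspotDataset",
    "normalize_sequence",
    "label_from_ddg",
    "dataset_summary",
]

#: The 20 standard amino acids in alphabetical one-letter order.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Catch-all symbol for every non-standard residue letter (B, Z, J, U, O, *...).
UNKNOWN_AA = "X"
#: The 21-symbol residue alphabet; 'X' deliberately last (one-hot column 20).
ALPHABET = STANDARD_AA + UNKNOWN_AA

HOTSPOT = "hotspot"
NON_HOTSPOT = "non_hotspot"

#: ddG cutoff in kcal/mol above which an interface residue is a hot spot.
DDG_THRESHOLD = 2.0

_ALPHABET_SET = frozenset(ALPHABET)


def normalize_sequence(seq: str) -> str:
    """Uppercase ``seq`` and map any letter outside the 20 standard amino
    acids to the catch-all symbol ``'X'``."""
    up = seq.upper()
    return "".join(c if c in _ALPHABET_SET else UNKNOWN_AA for c in up)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an identifier (e.g. PDB id + chain)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - _ALPHABET_SET
        if bad:
            raise ValueError(
                f"protein {self.id!r}: symbols {sorted(bad)} outside the "
                f"21-letter alphabet; normalize_sequence() first"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ResidueAnnotation:
    """One annotated residue: 1-based position, optional wild-type letter,
    optional ddG (kcal/mol) and/or binary label."""

    protein_id: str
    position: int  # 1-based, as in residue numbering like "172K"
    wild_type: str | None = None
    ddg: float | None = None
    label: str | None = None  # HOTSPOT / NON_HOTSPOT / None (= unknown)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(
                f"{self.protein_id}: position {self.position} below 1 "
                "(positions are 1-based)"
            )
        if self.label is not None and self.label not in (HOTSPOT, NON_HOTSPOT):
            raise ValueError(f"unknown label {self.label!r}")
        if self.ddg is not None and not math.isfinite(self.ddg):
            raise ValueError(f"{self.protein_id}:{self.position}: non-finite ddg")

    def effective_label(self, threshold: float = DDG_THRESHOLD) -> str | None:
        """The explicit label, falling back to the ddG rule."""
        if self.label is not None:
            return self.label
        if self.ddg is not None:
            return label_from_ddg(self.ddg, threshold)
        return None


def label_from_ddg(ddg: float, threshold: float = DDG_THRESHOLD) -> str:
    """Binary hotspot call from a ddG value.

    Hot spot iff ddG strictly exceeds ``threshold`` (default 2 kcal/mol);
    a tie at exactly the threshold is a non-hotspot.
    """
    if not math.isfinite(ddg):
        raise ValueError("ddg must be finite")
    return HOTSPOT if ddg > threshold else NON_HOTSPOT


@dataclass
class HotspotDataset:
    """A corpus of proteins plus residue annotations."""

    proteins: dict[str, ProteinRecord] = field(default_factory=dict)
    annotations: list[ResidueAnnotation] = field(default_factory=list)

    def validate(self, wild_type_mismatch: str = "error") -> list[str]:
        """Check referential integrity and wild-type consistency.

        ``wild_type_mismatch`` is ``"error"`` (raise) or ``"warn"`` (collect);
        real datasets contain numbering discrepancies, hence the downgrade.
        Returns the list of warning messages.
        """
        if wild_type_mismatch not in ("error", "warn"):
            raise ValueError("wild_type_mismatch must be 'error' or 'warn'")
        warnings: list[str] = []
        for ann in self.annotations:
            prot = self.proteins.get(ann.protein_id)
            if prot is None:
                raise ValueError(f"annotation references unknown protein {ann.protein_id!r}")
            if ann.position > prot.length:
                raise ValueError(
                    f"{ann.protein_id}: position {ann.position} beyond length {prot.length}"
                )
            if ann.wild_type is not None:
                actual = prot.sequence[ann.position - 1]
                if actual != ann.wild_type:
                    msg = (
                        f"{ann.protein_id}:{ann.position}: wild type "
                        f"{ann.wild_type!r} does not match sequence {actual!r}"
                    )
                    if wild_type_mismatch == "error":
                        raise ValueError(msg)
                    warnings.append(msg)
        return warnings

    def counts(self, threshold: float = DDG_THRESHOLD) -> tuple[int, int]:
        """(n_hotspot, n_non_hotspot) over annotations with a known label."""
        n_hot = n_non = 0
        for ann in self.annotations:
            lab = ann.effective_label(threshold)
            if lab == HOTSPOT:
                n_hot += 1
            elif lab == NON_HOTSPOT:
                n_non += 1
        return n_hot, n_non


def dataset_summary(ds: HotspotDataset) -> tuple[int, int, int | None]:
    """Class tallies and the floor of the non-hotspot : hotspot ratio.

    The benchmark corpus has 349 hotspots vs 22244 non-hotspots, a ratio
    floor of 63 — the stride used for interval subsampling of negatives.
    Returns ``(n_hotspot, n_non_hotspot, ratio_floor)``; the ratio is None
    when there are no hotspots.
    """
    n_hot, n_non = ds.counts()
    ratio = n_non // n_hot if n_hot > 0 else None
    return n_hot, n_non, ratio
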