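"""Synthetic fixtures: motif-planted labeled proteins and Gaussian clouds.

The protein generator emulates the structure of a hot-spot corpus without
any real energetics: each random sequence carries one planted short motif,
the residue at the motif center is annotated as a hotspot, and randomly
sampled off-motif residues are annotated as non-hotspots at a configurable
imbalance ratio (default 1:63, mirroring the real corpus).  Because the
label depends only on window content, a window-based classifier can in
principle solve the task — making end-to-end recovery a meaningful check of
the whole pipeline.  Annotations carry ddG values consistent with their
labels (> 2 kcal/mol for hotspots) so the labeling rule is exercised too.

The Gaussian feature clouds exercise SMOTE's k-NN interpolation geometry in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import HOTSPOT, NON_HOTSPOT, STANDARD_AA, HotspotDataset, ProteinRecord, ResidueAnnotation

__all__ = ["SyntheticProteinSpec", "FeatureCloudSpec", "generate_proteins", "generate_feature_cloud"]


@dataclass(frozen=True)
class SyntheticProteinSpec:
    """Study conditions for the motif-planted corpus.

    Defaults: 150 proteins of length 80-120, a 5-residue motif, 5% per-
    position substitution noise inside the motif, no background label noise,
    and the 1:63 class imbalance of the real corpus.
    """

    n_proteins: int = 150
    length_range: tuple[int, int] = (80, 120)
    motif: str = "WCHKY"
    substitution_noise: float = 0.05
    background_hotspot_rate: float = 0.0
    imbalance_ratio: int = 63
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not 0 < lo <= hi:
            raise ValueError("length_range must satisfy 0 < min <= max")
        if len(self.motif) % 2 == 0 or len(self.motif) >= lo:
            raise ValueError("motif length must be odd and shorter than the minimum protein")
        if any(c not in STANDARD_AA for c in self.motif):
            raise ValueError("motif must use the 20 standard letters")
        for name, p in (
            ("substitution_noise", self.substitution_noise),
            ("background_hotspot_rate", self.background_hotspot_rate),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if self.imbalance_ratio < 1:
            raise ValueError("imbalance_ratio must be >= 1")


@dataclass(frozen=True)
class FeatureCloudSpec:
    """Two isotropic Gaussian clusters (minority, majority)."""

    n_minority: int = 50
    n_majority: int = 200
    dim: int = 8
    minority_mean: float = 0.0
    majority_mean: float = 4.0
    spread: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.spread <= 0:
            raise ValueError("spread must be positive")


def generate_proteins(spec: SyntheticProteinSpec) -> HotspotDataset:
    """Random sequences with one planted motif each; hotspot = motif center.

    Substitution noise corrupts individual motif letters before planting
    (labels are unchanged, so noisy positives carry degraded signal).
    Non-hotspot annotations are drawn uniformly from off-motif positions
    across the corpus to reach imbalance_ratio negatives per positive;
    ``background_hotspot_rate`` flips each annotation's label independently.
    Deterministic under the seed.  ddG values are sampled consistent with
    each final label.
    """
    rng = np.random.default_rng(spec.seed)
    letters = np.array(list(STANDARD_AA))
    half = len(spec.motif) // 2
    proteins: dict[str, ProteinRecord] = {}
    pos_keys: list[tuple[str, int]] = []  # (protein_id, 1-based center)
    neg_candidates: list[tuple[str, int]] = []

    for i in range(spec.n_proteins):
        pid = f"syn{i:04d}"
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        seq = rng.choice(letters, size=length)
        start = int(rng.integers(0, length - len(spec.motif) + 1))
        motif = np.array(list(spec.motif))
        noise = rng.random(len(motif)) < spec.substitution_noise
        motif[noise] = rng.choice(letters, size=int(noise.sum()))
        seq[start : start + len(motif)] = motif
        sequence = "".join(seq)
        proteins[pid] = ProteinRecord(id=pid, sequence=sequence)
        center = start + half  # 0-based
        pos_keys.append((pid, center + 1))
        motif_span = set(range(start, start + len(motif)))
        neg_candidates.extend((pid, j + 1) for j in range(length) if j not in motif_span)

    n_neg = spec.imbalance_ratio * len(pos_keys)
    if n_neg > len(neg_candidates):
        raise ValueError(
            f"imbalance_ratio {spec.imbalance_ratio} needs {n_neg} negatives but only "
            f"{len(neg_candidates)} off-motif residues exist; lengthen proteins"
        )
    chosen = rng.choice(len(neg_candidates), size=n_neg, replace=False)
    neg_keys = [neg_candidates[int(j)] for j in sorted(chosen)]

    annotations: list[ResidueAnnotation] = []
    for keys, base_label in ((pos_keys, HOTSPOT), (neg_keys, NON_HOTSPOT)):
        for pid, pos in keys:
            label = base_label
            if spec.background_hotspot_rate and rng.random() < spec.background_hotspot_rate:
                label = NON_HOTSPOT if label == HOTSPOT else HOTSPOT
            if label == HOTSPOT:
                # strictly above the 2 kcal/mol threshold, also after rounding
                ddg = max(round(2.0 + float(rng.exponential(1.5)), 3), 2.001)
            else:
                ddg = float(rng.uniform(-1.0, 2.0))
            annotations.append(
                ResidueAnnotation(
                    protein_id=pid,
                    position=pos,
                    wild_type=proteins[pid].sequence[pos - 1],
                    ddg=round(ddg, 3),
                    label=label,
                )
            )
    annotations.sort(key=lambda a: (a.protein_id, a.position))
    return HotspotDataset(proteins=proteins, annotations=annotations)


def generate_feature_cloud(spec: FeatureCloudSpec) -> tuple[np.ndarray, np.ndarray]:
    """(minority, majority) matrices from two isotropic Gaussians."""
    rng = np.random.default_rng(spec.seed)
    minority = rng.normal(spec.minority_mean, spec.spread, size=(spec.n_minority, spec.dim))
    majority = rng.normal(spec.majority_mean, spec.spread, size=(spec.n_majority, spec.dim))
    return minority, majority
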