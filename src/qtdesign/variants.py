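"""SNP filtering, minor allele frequencies, and the rare-variant burden score.

Monomorphic SNPs are excluded; the remainder are classified rare when their
folded MAF is strictly below a threshold (default 3%).  The burden score for
an individual is the total count of minor alleles across all rare SNPs in the
gene; the common SNP (largest common MAF) is analyzed separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VariantPanel",
    "compute_maf",
    "minor_allele_dosage",
    "filter_and_classify",
    "rare_variant_score",
]

RARE_THRESHOLD = 0.03


@dataclass
class VariantPanel:
    """Polymorphic SNPs with MAFs and rare/common classification."""

    kept_snps: list[str]
    mafs: np.ndarray
    rare_mask: np.ndarray  # rare iff maf < rare_threshold (strict)
    flipped: np.ndarray  # True where the coded allele was the major allele
    common_snp: str | None  # label of the separately analyzed common SNP
    rare_threshold: float = RARE_THRESHOLD

    @property
    def rare_snps(self) -> list[str]:
        return [s for s, r in zip(self.kept_snps, self.rare_mask) if r]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp": self.kept_snps,
                "maf": self.mafs,
                "class": np.where(self.rare_mask, "rare", "common"),
            }
        )


def compute_maf(dosage_column: np.ndarray) -> tuple[float, bool]:
    """Folded minor allele frequency of one dosage column.

    Returns ``(maf, flipped)`` where ``maf = sum(dosage)/(2n)`` complemented
    to <= 0.5 and ``flipped`` is True when the coded allele is the major one.
    """
    col = np.asarray(dosage_column)
    if col.size == 0:
        raise ValueError("empty dosage column")
    freq = col.sum() / (2 * col.size)
    if freq > 0.5:
        return 1.0 - freq, True
    return float(freq), False


def minor_allele_dosage(dosage_column: np.ndarray) -> np.ndarray:
    """Dosage recoded so the counted allele is the minor one."""
    col = np.asarray(dosage_column)
    _, flipped = compute_maf(col)
    return 2 - col if flipped else col


def _as_matrix(genotypes) -> tuple[np.ndarray, list[str]]:
    if isinstance(genotypes, pd.DataFrame):
        return genotypes.to_numpy(), list(genotypes.columns)
    g = np.asarray(genotypes)
    return g, [f"SNP{j + 1}" for j in range(g.shape[1])]


def filter_and_classify(
    genotypes, rare_threshold: float = RARE_THRESHOLD
) -> VariantPanel:
    """Drop monomorphic SNPs and classify the rest as rare or common.

    ``genotypes`` is an individuals x SNPs dosage matrix (DataFrame column
    names become SNP labels).  Classification is strict: maf < threshold is
    rare, maf >= threshold common.  The common SNP reported in the panel is
    the common variant with the largest MAF (None when all SNPs are rare).
    """
    if not (0.0 < rare_threshold < 0.5):
        raise ValueError("rare_threshold must be in (0, 0.5)")
    g, labels = _as_matrix(genotypes)
    mafs, flips = zip(*(compute_maf(g[:, j]) for j in range(g.shape[1])))
    mafs, flips = np.array(mafs), np.array(flips)
    keep = mafs > 0.0
    if not keep.any():
        raise ValueError("all SNPs are monomorphic; empty panel")
    mafs, flips = mafs[keep], flips[keep]
    kept = [s for s, k in zip(labels, keep) if k]
    rare = mafs < rare_threshold
    common_snp = None
    if (~rare).any():
        common_idx = np.flatnonzero(~rare)
        common_snp = kept[common_idx[np.argmax(mafs[common_idx])]]
    return VariantPanel(kept_snps=kept, mafs=mafs, rare_mask=rare,
                        flipped=flips, common_snp=common_snp,
                        rare_threshold=rare_threshold)


def rare_variant_score(genotypes, panel: VariantPanel) -> np.ndarray:
    """Per-individual total count of minor alleles across the rare SNPs."""
    if not panel.rare_mask.any():
        raise ValueError("panel contains no rare SNPs")
    g, labels = _as_matrix(genotypes)
    col_of = {s: j for j, s in enumerate(labels)}
    score = np.zeros(g.shape[0], dtype=np.int64)
    for snp, rare, flipped in zip(panel.kept_snps, panel.rare_mask, panel.flipped):
        if rare:
            col = g[:, col_of[snp]]
            score += (2 - col) if flipped else col
    return score
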