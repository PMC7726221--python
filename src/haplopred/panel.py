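"""Phased genotype container shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Required columns of a SNP map frame (positions are 1-based, as in VCF).
SNP_MAP_COLUMNS = ("chrom", "pos", "ref", "alt")


def validate_snp_map(snp_map: pd.DataFrame) -> None:
    """Check column presence and strictly increasing positions per chromosome."""
    missing = [c for c in SNP_MAP_COLUMNS if c not in snp_map.columns]
    if missing:
        raise ValueError(f"SNP map missing columns: {missing}")
    for chrom, grp in snp_map.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"positions not strictly increasing on {chrom}")


@dataclass
class GenotypePanel:
    """Phased diploid genotypes for n individuals over m mapped SNPs.

    ``haplotypes`` is a (2n, m) int8 array of allele indicators (0 = ref,
    1 = alt); rows 2i and 2i+1 are the two phased chromosomes of individual
    i. ``snp_map`` carries chrom, pos (1-based), ref, alt, and is augmented
    with the realized alt-allele frequency (``freq``) and minor allele
    frequency (``maf``) on construction.
    """

    haplotypes: np.ndarray
    snp_map: pd.DataFrame
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D (2n, m) array")
        if self.haplotypes.shape[0] % 2 != 0:
            raise ValueError("haplotype row count must be even (2 per individual)")
        if self.haplotypes.shape[0] < 4:
            raise ValueError("need at least 2 individuals")
        if len(self.snp_map) != self.haplotypes.shape[1]:
            raise ValueError("snp_map length does not match haplotype columns")
        validate_snp_map(self.snp_map)
        if not self.samples:
            self.samples = [f"ind{i:05d}" for i in range(self.n_individuals)]
        if len(self.samples) != self.n_individuals:
            raise ValueError("sample list does not match individual count")
        self.snp_map = self.snp_map.reset_index(drop=True).copy()
        freq = self.haplotypes.mean(axis=0)
        self.snp_map["freq"] = freq
        self.snp_map["maf"] = np.minimum(freq, 1.0 - freq)

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]

    def dosages(self) -> np.ndarray:
        """(n, m) alt-allele dosage matrix in {0, 1, 2}."""
        return (self.haplotypes[0::2].astype(np.int16) + self.haplotypes[1::2]).astype(
            np.int8
        )

    def alt_freqs(self) -> np.ndarray:
        return self.snp_map["freq"].to_numpy()

    def subset_snps(self, indices: np.ndarray) -> "GenotypePanel":
        """New panel restricted to the given SNP column indices (order kept)."""
        indices = np.asarray(indices, dtype=int)
        return GenotypePanel(
            haplotypes=self.haplotypes[:, indices],
            snp_map=self.snp_map.iloc[indices][list(SNP_MAP_COLUMNS)],
            samples=list(self.samples),
        )
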