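"""Haplotype block construction and block-allele enumeration.

A haplotype block is a set of consecutive SNPs treated as one multi-allelic
locus; every distinct phased allele string observed across the 2n sample
chromosomes is one "allele" of that locus.  Blocks are defined either by
structural rules (fixed chromosome distance in kb, fixed SNP count) or by
annotation intervals (genes, coding genes, noncoding genes, ChIP-seq sites)
extended by a flank and split into bounded chunks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import GenotypePanel, SNP_MAP_COLUMNS, validate_snp_map


@dataclass
class HaplotypeBlock:
    block_id: str
    chrom: str
    snp_indices: np.ndarray  # global SNP-map row indices, ascending
    span_bp: int
    source: str  # distance | count | gene | coding | noncoding | chipseq
    # filled by enumerate_haplotypes:
    allele_strings: list = field(default_factory=list)
    allele_counts: np.ndarray | None = None
    allele_freqs: np.ndarray | None = None
    hap_allele_index: np.ndarray | None = None  # (2n,) allele index per chromosome

    @property
    def n_snps(self) -> int:
        return len(self.snp_indices)

    @property
    def n_alleles(self) -> int:
        return len(self.allele_strings)


@dataclass
class HaplotypeBlockSet:
    blocks: list
    source: str

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self):
        return iter(self.blocks)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (
                b.block_id,
                b.chrom,
                int(b.snp_indices[0]),
                int(b.snp_indices[-1]),
                b.n_snps,
                b.span_bp,
                b.source,
            )
            for b in self.blocks
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "block_id",
                "chrom",
                "start_snp",
                "end_snp",
                "n_snps",
                "span_bp",
                "source",
            ],
        )


@dataclass
class BlockStatistics:
    """Summary fields of a block set, mirroring the standard block tables."""

    source: str
    n_blocks: int
    total_haplotypes: int
    avg_haplotypes_per_block: float
    min_snps_per_block: int
    max_snps_per_block: int
    avg_snps_per_block: float
    min_span_kb: float
    max_span_kb: float
    avg_span_kb: float
    coverage_mb: float
    coverage_pct: float
    flank_extended_coverage_mb: float
    flank_extended_coverage_pct: float

    def to_series(self) -> pd.Series:
        return pd.Series(self.__dict__)


def subset_snps(
    snp_map: pd.DataFrame, maf_min: float, target_count: int | None = None
) -> pd.DataFrame:
    """MAF filter (inclusive at the boundary) plus optional uniform thinning.

    Removes SNPs with MAF < ``maf_min``; if ``target_count`` is given the
    survivors are thinned to that many SNPs by uniform index stride,
    preserving order.  The returned frame keeps the original row index so
    panels can be subset with it.
    """
    if not (0 <= maf_min < 0.5):
        raise ValueError("maf_min must be in [0, 0.5)")
    if "maf" not in snp_map.columns:
        raise ValueError("snp_map must carry a 'maf' column")
    kept = snp_map[snp_map["maf"] >= maf_min]
    if target_count is not None:
        if target_count > len(kept):
            raise ValueError(
                f"target_count {target_count} exceeds surviving SNPs ({len(kept)})"
            )
        sel = np.unique(np.round(np.linspace(0, len(kept) - 1, target_count)).astype(int))
        kept = kept.iloc[sel]
    return kept


def blocks_fixed_distance(snp_map: pd.DataFrame, window_kb: float) -> HaplotypeBlockSet:
    """Partition each chromosome into consecutive fixed-width windows.

    Windows are laid on absolute coordinates (window index = pos //
    window_bp); SNPs are assigned by position and windows with fewer than
    two SNPs yield no block.  The recorded span of every emitted block is
    the window width.
    """
    if window_kb <= 0:
        raise ValueError("window_kb must be positive")
    if len(snp_map) == 0:
        raise ValueError("empty SNP map")
    validate_snp_map(snp_map)
    window_bp = int(round(window_kb * 1000))

    blocks = []
    for chrom, grp in snp_map.groupby("chrom", sort=False):
        widx = grp["pos"].to_numpy() // window_bp
        for w in np.unique(widx):
            members = grp.index.to_numpy()[widx == w]
            if members.size < 2:
                continue
            blocks.append(
                HaplotypeBlock(
                    block_id=f"dist{window_kb:g}kb_{chrom}_{w}",
                    chrom=str(chrom),
                    snp_indices=members,
                    span_bp=window_bp,
                    source="distance",
                )
            )
    return HaplotypeBlockSet(blocks=blocks, source="distance")


def blocks_fixed_count(snp_map: pd.DataFrame, s: int) -> HaplotypeBlockSet:
    """Consecutive groups of exactly ``s`` SNPs per chromosome.

    When a chromosome's SNP count is not divisible by ``s`` the final block
    consists of the chromosome's last ``s`` SNPs and may overlap the
    penultimate block, so every emitted block has exactly ``s`` SNPs and
    the per-chromosome block count is ceil(m_c / s).  Chromosomes with
    fewer than ``s`` SNPs are skipped with a warning.
    """
    if s < 2:
        raise ValueError("s must be >= 2")
    validate_snp_map(snp_map)

    blocks = []
    for chrom, grp in snp_map.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        m_c = idx.size
        if m_c < s:
            warnings.warn(f"chromosome {chrom} has {m_c} < {s} SNPs; skipped")
            continue
        n_blocks = int(np.ceil(m_c / s))
        for b in range(n_blocks):
            start = b * s
            if start + s > m_c:
                start = m_c - s  # trailing overlap keeps block size exactly s
            members = idx[start : start + s]
            span = int(pos[start + s - 1] - pos[start])
            blocks.append(
                HaplotypeBlock(
                    block_id=f"count{s}_{chrom}_{b}",
                    chrom=str(chrom),
                    snp_indices=members,
                    span_bp=span,
                    source="count",
                )
            )
    return HaplotypeBlockSet(blocks=blocks, source="count")


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Union of [start, end) intervals; returns merged, sorted array."""
    if len(intervals) == 0:
        return np.empty((0, 2), dtype=int)
    order = np.argsort(intervals[:, 0], kind="stable")
    merged = [list(intervals[order[0]])]
    for i in order[1:]:
        s, e = intervals[i]
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=int)


def blocks_from_intervals(
    snp_map: pd.DataFrame,
    intervals: pd.DataFrame,
    flank_kb: float = 2.0,
    split_kb: float = 150.0,
    source: str | None = None,
) -> HaplotypeBlockSet:
    """Blocks from annotation intervals (BED convention, 0-based half-open).

    Each interval is extended by ``flank_kb`` on both ends (clipped at
    position 1), overlapping extended intervals of the same class are
    merged, merged intervals longer than ``split_kb`` are cut into
    consecutive chunks of at most ``split_kb``, SNPs are assigned by
    position, and chunks with fewer than two SNPs are dropped.  A block's
    span is the distance between its first and last SNP.

    ``intervals`` needs columns chrom, start, end and optionally ``cls``;
    when ``source`` is given only intervals of that class are used.
    """
    validate_snp_map(snp_map)
    if (intervals["end"] <= intervals["start"]).any():
        raise ValueError("malformed intervals: end <= start")
    if source is not None and "cls" in intervals.columns:
        intervals = intervals[intervals["cls"] == source]
    label = source or "gene"
    flank = int(round(flank_kb * 1000))
    split = int(round(split_kb * 1000))

    blocks = []
    counter = 0
    for chrom, grp in intervals.groupby("chrom", sort=False):
        chrom_snps = snp_map[snp_map["chrom"] == chrom]
        if len(chrom_snps) == 0:
            continue
        pos = chrom_snps["pos"].to_numpy()
        gidx = chrom_snps.index.to_numpy()

        # BED half-open -> 1-based inclusive [start+1, end], then flank
        ext = np.stack(
            [
                np.maximum(grp["start"].to_numpy() + 1 - flank, 1),
                grp["end"].to_numpy() + flank,
            ],
            axis=1,
        )
        for lo, hi in merge_intervals(ext):
            chunk_lo = lo
            while chunk_lo <= hi:
                chunk_hi = min(chunk_lo + split - 1, hi)
                inside = (pos >= chunk_lo) & (pos <= chunk_hi)
                members = gidx[inside]
                if members.size >= 2:
                    p = pos[inside]
                    blocks.append(
                        HaplotypeBlock(
                            block_id=f"{label}_{chrom}_{counter}",
                            chrom=str(chrom),
                            snp_indices=members,
                            span_bp=int(p[-1] - p[0]),
                            source=label,
                        )
                    )
                    counter += 1
                chunk_lo = chunk_hi + 1
    return HaplotypeBlockSet(blocks=blocks, source=label)


def enumerate_haplotypes(
    blockset: HaplotypeBlockSet, panel: GenotypePanel
) -> HaplotypeBlockSet:
    """Fill each block's haplotype-allele catalog from the phased panel.

    For every block the distinct allele strings over the block's SNPs
    across all 2n phased chromosomes form the catalog; frequencies are
    count / 2n.  Rare haplotypes are retained (no haplotype-level
    frequency filtering).  Positional SNP-map indices are resolved against
    the panel's map, so a blockset built on the panel's own map works
    directly.
    """
    n_chrom = panel.haplotypes.shape[0]
    for block in blockset.blocks:
        cols = np.asarray(block.snp_indices, dtype=int)
        if cols.max() >= panel.n_snps:
            raise IndexError(f"block {block.block_id} references SNPs beyond panel")
        sub = np.ascontiguousarray(panel.haplotypes[:, cols])
        uniq, inverse, counts = np.unique(
            sub, axis=0, return_inverse=True, return_counts=True
        )
        block.allele_strings = ["".join(map(str, row)) for row in uniq]
        block.allele_counts = counts
        block.allele_freqs = counts / n_chrom
        block.hap_allele_index = inverse.astype(np.int32)
    return blockset


def block_statistics(
    blockset: HaplotypeBlockSet,
    snp_map: pd.DataFrame,
    genome_length_bp: int | None = None,
    flank_kb: float = 2.0,
) -> BlockStatistics:
    """Aggregate block-set statistics (totals, averages, spans, coverage).

    Coverage is the union of block spans over the genome length (sum of
    per-chromosome spans of the SNP map unless ``genome_length_bp`` is
    given); flank-extended coverage extends every block span by
    ``flank_kb`` on both sides before taking the union.
    """
    blocks = blockset.blocks
    if not blocks:
        raise ValueError("empty block set")
    for b in blocks:
        if b.allele_counts is None:
            raise ValueError("alleles not enumerated; call enumerate_haplotypes first")

    n_alleles = np.array([b.n_alleles for b in blocks])
    n_snps = np.array([b.n_snps for b in blocks])
    spans = np.array([b.span_bp for b in blocks], dtype=float)

    if genome_length_bp is None:
        genome_length_bp = int(
            snp_map.groupby("chrom")["pos"].agg(lambda p: p.max() - p.min() + 1).sum()
        )
    flank = flank_kb * 1000

    def union_len(extend: float) -> float:
        total = 0.0
        by_chrom: dict[str, list] = {}
        for b in blocks:
            pos = snp_map.loc[b.snp_indices, "pos"]
            lo = max(float(pos.min()) - extend, 1.0)
            hi = float(pos.max()) + extend
            by_chrom.setdefault(b.chrom, []).append((lo, hi + 1))
        for ivs in by_chrom.values():
            merged = merge_intervals(np.asarray(ivs, dtype=float).astype(int))
            total += float((merged[:, 1] - merged[:, 0]).sum())
        return total

    cov = union_len(0.0)
    cov_ext = union_len(flank)
    return BlockStatistics(
        source=blockset.source,
        n_blocks=len(blocks),
        total_haplotypes=int(n_alleles.sum()),
        avg_haplotypes_per_block=float(n_alleles.mean()),
        min_snps_per_block=int(n_snps.min()),
        max_snps_per_block=int(n_snps.max()),
        avg_snps_per_block=float(n_snps.mean()),
        min_span_kb=float(spans.min() / 1000),
        max_span_kb=float(spans.max() / 1000),
        avg_span_kb=float(spans.mean() / 1000),
        coverage_mb=cov / 1e6,
        coverage_pct=100.0 * cov / genome_length_bp,
        flank_extended_coverage_mb=cov_ext / 1e6,
        flank_extended_coverage_pct=100.0 * cov_ext / genome_length_bp,
    )
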