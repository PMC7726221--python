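from collections import Counter

import numpy as np
import pandas as pd
import pytest

from haplopred import (
    GenotypePanel,
    block_statistics,
    blocks_fixed_count,
    blocks_fixed_distance,
    blocks_from_intervals,
    enumerate_haplotypes,
    subset_snps,
)
from haplopred.haploblock import merge_intervals
from conftest import make_snp_map


def union_length_oracle(intervals):
    """Independent interval-union routine: sweep over sorted endpoints."""
    events = []
    for s, e in intervals:
        events.append((s, 1))
        events.append((e, -1))
    events.sort()
    total = depth = 0
    start = None
    for x, d in events:
        if depth == 0 and d == 1:
            start = x
        depth += d
        if depth == 0:
            total += x - start
    return total


class TestSubsetSnps:
    def test_maf_boundary_is_inclusive(self):
        m = make_snp_map({"1": [100, 200, 300]})
        m["maf"] = [0.01, 0.05, 0.3]
        kept = subset_snps(m, maf_min=0.05)
        assert len(kept) == 2
        assert list(kept["maf"]) == [0.05, 0.3]

    def test_zero_threshold_is_identity(self):
        m = make_snp_map({"1": range(100, 1100, 10)})
        assert subset_snps(m, maf_min=0.0).equals(m)

    def test_thinning_stride_is_uniform(self):
        m = make_snp_map({"1": range(1, 10_001)})
        kept = subset_snps(m, maf_min=0.0, target_count=1000)
        assert len(kept) == 1000
        gaps = np.diff(kept.index.to_numpy())
        assert gaps.max() - gaps.min() <= 1

    def test_target_count_too_large_rejected(self):
        m = make_snp_map({"1": [100, 200]})
        with pytest.raises(ValueError):
            subset_snps(m, maf_min=0.0, target_count=5)


class TestFixedDistance:
    def test_hand_enumerated_window_assignment(self):
        m = make_snp_map({"1": [1000, 3000, 6000, 12000, 20000]})
        bs = blocks_fixed_distance(m, window_kb=10)
        assert len(bs) == 1
        assert list(m.loc[bs.blocks[0].snp_indices, "pos"]) == [1000, 3000, 6000]

    def test_window_larger_than_chromosome_gives_one_block(self):
        m = make_snp_map({"1": [1000, 3000, 6000, 12000, 20000]})
        bs = blocks_fixed_distance(m, window_kb=1000)
        assert len(bs) == 1 and bs.blocks[0].n_snps == 5

    def test_span_field_equals_window_width(self):
        m = make_snp_map({"1": range(1000, 100_000, 700)})
        bs = blocks_fixed_distance(m, window_kb=20)
        assert all(b.span_bp == 20_000 for b in bs)

    def test_doubling_window_never_increases_blocks_on_dense_maps(self):
        # coarsening holds when every occupied window has >= 2 SNPs
        rng = np.random.default_rng(41)
        for _ in range(20):
            pos = np.sort(rng.choice(200_000, size=400, replace=False)) + 1
            m = make_snp_map({"1": pos})
            for w in (5, 10, 20):
                fine = blocks_fixed_distance(m, w)
                if any(b.n_snps < 2 for b in fine):
                    continue
                assert len(blocks_fixed_distance(m, 2 * w)) <= len(fine)

    def test_snps_appear_in_at_most_one_block(self):
        m = make_snp_map({"1": range(1000, 300_000, 1500), "2": range(500, 80_000, 900)})
        bs = blocks_fixed_distance(m, window_kb=25)
        all_idx = np.concatenate([b.snp_indices for b in bs])
        assert len(all_idx) == len(set(all_idx))

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            blocks_fixed_distance(make_snp_map({"1": []}), 10)


class TestFixedCount:
    def test_trailing_overlap_rule_seven_by_three(self):
        m = make_snp_map({"1": range(100, 800, 100)})  # 7 SNPs
        bs = blocks_fixed_count(m, 3)
        assert len(bs) == 3
        members = [list(b.snp_indices) for b in bs]
        assert members == [[0, 1, 2], [3, 4, 5], [4, 5, 6]]

    def test_divisible_count_gives_disjoint_blocks(self):
        m = make_snp_map({"1": range(100, 1300, 100)})  # 12 SNPs
        bs = blocks_fixed_count(m, 4)
        assert len(bs) == 3
        all_idx = np.concatenate([b.snp_indices for b in bs])
        assert len(all_idx) == len(set(all_idx)) == 12

    @pytest.mark.parametrize("s", [2, 3, 5, 9])
    def test_every_block_has_exactly_s_snps(self, s):
        rng = np.random.default_rng(43)
        pos1 = np.sort(rng.choice(1_000_000, size=137, replace=False)) + 1
        pos2 = np.sort(rng.choice(500_000, size=61, replace=False)) + 1
        m = make_snp_map({"1": pos1, "2": pos2})
        bs = blocks_fixed_count(m, s)
        sizes = {b.n_snps for b in bs}
        assert sizes == {s}
        expected = int(np.ceil(137 / s) + np.ceil(61 / s))
        assert len(bs) == expected

    def test_short_chromosome_skipped_with_warning(self):
        m = make_snp_map({"1": [100, 200], "2": range(100, 1100, 100)})
        with pytest.warns(UserWarning, match="skipped"):
            bs = blocks_fixed_count(m, 5)
        assert all(b.chrom == "2" for b in bs)

    def test_s_below_two_rejected(self):
        with pytest.raises(ValueError):
            blocks_fixed_count(make_snp_map({"1": [1, 2, 3]}), 1)


class TestIntervalBlocks:
    def test_large_interval_split_into_chunks(self):
        # 400-kb interval + 2-kb flanks = 404 kb -> chunks 150/150/104
        pos = np.arange(95_000, 520_000, 500)
        m = make_snp_map({"1": pos})
        iv = pd.DataFrame(
            {"chrom": ["1"], "start": [100_000], "end": [500_000], "name": ["g"], "cls": ["coding"]}
        )
        bs = blocks_from_intervals(m, iv, flank_kb=2, split_kb=150)
        assert len(bs) == 3
        assert all(b.span_bp <= 150_000 for b in bs)

    def test_single_snp_interval_emits_no_block(self):
        m = make_snp_map({"1": [50_000, 400_000]})
        iv = pd.DataFrame(
            {"chrom": ["1"], "start": [45_000], "end": [55_000], "name": ["g"], "cls": ["coding"]}
        )
        assert len(blocks_from_intervals(m, iv)) == 0

    def test_overlapping_intervals_merged_before_chunking(self):
        m = make_snp_map({"1": np.arange(1_000, 120_000, 400)})
        iv = pd.DataFrame(
            {
                "chrom": ["1", "1"],
                "start": [10_000, 40_000],
                "end": [50_000, 90_000],
                "name": ["a", "b"],
                "cls": ["coding", "coding"],
            }
        )
        bs = blocks_from_intervals(m, iv, flank_kb=2, split_kb=150)
        assert len(bs) == 1  # merged union fits in one chunk
        merged = merge_intervals(np.array([[8_001, 52_000], [38_001, 92_000]]))
        assert union_length_oracle(merged) == union_length_oracle(
            [[8_001, 52_000], [38_001, 92_000]]
        )

    def test_classes_kept_separate(self):
        m = make_snp_map({"1": np.arange(1_000, 60_000, 400)})
        iv = pd.DataFrame(
            {
                "chrom": ["1", "1"],
                "start": [10_000, 12_000],
                "end": [30_000, 32_000],
                "name": ["a", "b"],
                "cls": ["coding", "chipseq"],
            }
        )
        coding = blocks_from_intervals(m, iv, source="coding")
        chip = blocks_from_intervals(m, iv, source="chipseq")
        assert len(coding) == 1 and len(chip) == 1
        assert coding.blocks[0].source == "coding"

    def test_malformed_interval_rejected(self):
        m = make_snp_map({"1": [100, 200]})
        iv = pd.DataFrame(
            {"chrom": ["1"], "start": [500], "end": [400], "name": ["g"], "cls": ["coding"]}
        )
        with pytest.raises(ValueError, match="malformed"):
            blocks_from_intervals(m, iv)


class TestEnumerateHaplotypes:
    def test_direct_count_example(self):
        haps = np.array(
            [[0, 0, 1], [0, 1, 1], [0, 1, 0], [1, 1, 1]], dtype=np.int8
        )  # block over SNPs 0-1: "00","01","01","11"; SNP 2 is a singleton window
        snp_map = pd.DataFrame(
            {"chrom": "1", "pos": [100, 200, 1500], "ref": "A", "alt": "G"}
        )
        panel = GenotypePanel(haplotypes=haps, snp_map=snp_map)
        bs = blocks_fixed_distance(panel.snp_map, 1)
        assert len(bs) == 1
        enumerate_haplotypes(bs, panel)
        block = bs.blocks[0]
        assert sorted(block.allele_strings) == ["00", "01", "11"]
        by_string = dict(zip(block.allele_strings, block.allele_freqs))
        assert by_string == {"00": 0.25, "01": 0.5, "11": 0.25}

    def test_monomorphic_block_single_allele(self):
        haps = np.tile(np.array([1, 0, 1], dtype=np.int8), (6, 1))
        snp_map = pd.DataFrame(
            {"chrom": "1", "pos": [100, 200, 300], "ref": "A", "alt": "G"}
        )
        panel = GenotypePanel(haplotypes=haps, snp_map=snp_map)
        bs = enumerate_haplotypes(blocks_fixed_distance(panel.snp_map, 1), panel)
        assert bs.blocks[0].n_alleles == 1
        assert bs.blocks[0].allele_freqs[0] == 1.0

    def test_counts_match_string_hash_oracle(self, small_panel, small_blocks):
        for block in small_blocks:
            strings = [
                "".join(map(str, row))
                for row in small_panel.haplotypes[:, block.snp_indices]
            ]
            oracle = Counter(strings)
            assert dict(zip(block.allele_strings, block.allele_counts)) == oracle

    def test_allele_frequencies_sum_to_one(self, small_blocks):
        for block in small_blocks:
            assert abs(block.allele_freqs.sum() - 1.0) < 1e-12
            assert block.allele_counts.sum() == 200  # 2n chromosomes


class TestBlockStatistics:
    def test_toy_totals_and_average(self, toy_panel):
        bs = enumerate_haplotypes(blocks_fixed_count(toy_panel.snp_map, 2), toy_panel)
        stats = block_statistics(bs, toy_panel.snp_map)
        assert stats.total_haplotypes == sum(b.n_alleles for b in bs)
        assert stats.avg_haplotypes_per_block == pytest.approx(
            stats.total_haplotypes / stats.n_blocks
        )

    def test_average_snps_consistent(self, small_panel, small_blocks):
        stats = block_statistics(small_blocks, small_panel.snp_map)
        total_snps = sum(b.n_snps for b in small_blocks)
        assert stats.avg_snps_per_block == pytest.approx(
            total_snps / stats.n_blocks, abs=1e-9
        )

    def test_coverage_matches_union_oracle(self, small_panel, small_blocks):
        stats = block_statistics(small_blocks, small_panel.snp_map)
        ivs = []
        for b in small_blocks:
            pos = small_panel.snp_map.loc[b.snp_indices, "pos"]
            ivs.append((pos.min(), pos.max() + 1))
        genome = (
            small_panel.snp_map.groupby("chrom")["pos"]
            .agg(lambda p: p.max() - p.min() + 1)
            .sum()
        )
        expected_pct = 100 * union_length_oracle(ivs) / genome
        assert stats.coverage_pct == pytest.approx(expected_pct, rel=1e-9)
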