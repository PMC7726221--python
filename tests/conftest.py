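import numpy as np
import pandas as pd
import pytest

from haplopred import (
    GenotypePanel,
    SimConfig,
    blocks_fixed_distance,
    enumerate_haplotypes,
    simulate_genotypes,
)


@pytest.fixture(scope="session")
def small_panel():
    """100 individuals, ~200 SNPs on one chromosome, moderate LD."""
    config = SimConfig(
        n_individuals=100,
        chromosomes=[("1", 2_000_000)],
        snp_density=100,
        maf_spectrum=("uniform", 0.1, 0.5),
        ld_decay=0.6,
        seed=11,
    )
    return simulate_genotypes(config)


@pytest.fixture(scope="session")
def small_blocks(small_panel):
    blocks = blocks_fixed_distance(small_panel.snp_map, 100)
    return enumerate_haplotypes(blocks, small_panel)


@pytest.fixture()
def toy_panel():
    """Hand-built panel: 3 individuals x 4 SNPs with known haplotypes."""
    haplotypes = np.array(
        [
            [0, 0, 1, 0],
            [0, 1, 1, 1],
            [0, 1, 0, 1],
            [1, 1, 0, 0],
            [1, 0, 1, 0],
            [0, 1, 1, 1],
        ],
        dtype=np.int8,
    )
    snp_map = pd.DataFrame(
        {
            "chrom": ["1"] * 4,
            "pos": [100, 500, 900, 1500],
            "ref": ["A"] * 4,
            "alt": ["G"] * 4,
        }
    )
    return GenotypePanel(haplotypes=haplotypes, snp_map=snp_map)


def make_snp_map(positions_by_chrom):
    """SNP map from a {chrom: positions} dict, with a placeholder MAF."""
    frames = []
    for chrom, positions in positions_by_chrom.items():
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": sorted(positions),
                    "ref": "A",
                    "alt": "G",
                    "maf": 0.3,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
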