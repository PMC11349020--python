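"""Shared fixtures: small ground-truthed synthetic inputs.

Session scope keeps generator cost paid once; tests must not mutate the
fixture objects.
"""

import numpy as np
import pandas as pd
import pytest

from cellherit.simulate import (
    simulate_atac,
    simulate_expression,
    simulate_genome,
    simulate_gwas,
    simulate_ld_panel,
)


@pytest.fixture(scope="session")
def genome():
    return simulate_genome(n_chrom=2, genes_per_chrom=50,
                           chrom_length=10_000_000, seed=11)


@pytest.fixture(scope="session")
def panel(genome):
    return simulate_ld_panel(genome, m_snps=1_000, n_hap=200, seed=12)


@pytest.fixture(scope="session")
def null_stats(panel):
    return simulate_gwas(panel, None, 0.0, 10_000, seed=13)


@pytest.fixture(scope="session")
def counts(genome):
    return simulate_expression(
        genome, k_types=6, cells_per_type=60, marker_fraction=0.05,
        fold_change=8.0, seed=14,
    )


@pytest.fixture(scope="session")
def atac_genome():
    return simulate_genome(n_chrom=1, genes_per_chrom=30,
                           chrom_length=2_000_000, seed=15)


@pytest.fixture(scope="session")
def coverage(atac_genome):
    return simulate_atac(
        atac_genome, k_types=4, peaks_per_type=40, fold=10.0,
        background_rate=2.0, pseudo_cells_per_type=20,
        n_coaccess_pairs=2, seed=16,
    )


@pytest.fixture
def toy_genome():
    """Hand-placed genes for boundary arithmetic tests."""
    from cellherit.datatypes import GenomeModel

    genes = pd.DataFrame(
        {
            "gene_id": ["gA", "gB", "gC"],
            "chrom": ["chr1", "chr1", "chr2"],
            "start": [100_000, 300_000, 50_000],
            "end": [110_000, 320_000, 60_000],
            "strand": ["+", "-", "+"],
        }
    )
    chroms = pd.DataFrame({"chrom": ["chr1", "chr2"], "length": [1_000_000] * 2})
    return GenomeModel(chromosomes=chroms, genes=genes)


def toy_panel_at(positions, chrom="chr1", n_hap=50, seed=0):
    """A panel with SNPs at exact positions (random haplotypes)."""
    from cellherit.datatypes import LDPanel

    rng = np.random.default_rng(seed)
    positions = sorted(positions)
    snps = pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(len(positions))],
            "chrom": chrom,
            "pos": positions,
            "a1": "A",
            "a2": "G",
            "maf": 0.3,
        }
    )
    haps = rng.integers(0, 2, size=(n_hap, len(positions))).astype(np.uint8)
    haps[0] = 1  # guard against monomorphism
    haps[1] = 0
    return LDPanel(snps=snps, haplotypes=haps, blocks=[(0, len(positions))])
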