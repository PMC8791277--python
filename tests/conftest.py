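import numpy as np
import pytest

from proxiscape.simulate import SimulationConfig, plant_labeled_clusters, simulate_gene_universe
from proxiscape.types import GeneRecord, GeneTable, LabelStatus


@pytest.fixture(scope="session")
def small_genome():
    """Two 50 Mb chromosomes, 500 genes, no planted structure."""
    cfg = SimulationConfig(
        n_chroms=2, chrom_length_bp=50_000_000, n_genes=500, n_labeled=20,
        cluster_regions=[], cluster_fraction=0.0, seed=7,
    )
    return simulate_gene_universe(cfg), cfg


@pytest.fixture(scope="session")
def clustered_genome():
    """Planted-cluster study layout: 3 x 100 Mb, 3,000 genes, 60 labeled,
    two 5 Mb clusters holding an expected 80% of the labeled genes."""
    cfg = SimulationConfig(
        n_chroms=3, chrom_length_bp=100_000_000, n_genes=3_000, n_labeled=60,
        cluster_regions=[("chr1", 20_000_000, 25_000_000), ("chr2", 60_000_000, 65_000_000)],
        cluster_fraction=0.8, seed=11,
    )
    genes = simulate_gene_universe(cfg)
    plant = plant_labeled_clusters(genes, cfg)
    return genes, plant, cfg


def make_gene_table(midpoints_by_chrom, chrom_len=1_000_000, span=10, strand="+", tpms=None):
    """Tiny hand-built gene table: genes named g0, g1, ... in input order."""
    records, sizes = [], {}
    i = 0
    for chrom, mids in midpoints_by_chrom.items():
        sizes[chrom] = chrom_len
        for mid in mids:
            start = max(mid - span // 2, 0)
            tpm = tpms[i] if tpms else 1.0
            records.append(GeneRecord(f"g{i}", chrom, start, start + span, strand, tpm))
            i += 1
    return GeneTable(records=records, chrom_sizes=sizes)


@pytest.fixture
def gene_table_factory():
    return make_gene_table
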