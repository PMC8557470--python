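import numpy as np
import pytest

from admixscan import SimConfig, simulate_cohort
from admixscan.io import GenotypeMatrix, PopulationMap


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced admixed cohort with all planted signals (fast, shared)."""
    cfg = SimConfig(n_sites=8000, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """The full default cohort (study-scale density, all signals)."""
    return simulate_cohort(SimConfig(seed=1))


def neutral_config(seed: int) -> SimConfig:
    """Neutral cohort: no tract, no BS clusters, 60 samples, 5,000 sites."""
    cfg = SimConfig(n_sites=5000, chrom_length_bp=400_000, tract=None, bs_clusters=[], seed=seed)
    cfg.donor_pops = {"donorA": 15, "donorB": 15}
    cfg.hybrids[0].n_samples = 12
    cfg.hybrids[1].n_samples = 10
    return cfg


def toy_matrix(genotypes, pos=None, chrom="chr1", haplotypes=None, sample_prefix="s"):
    """Build a GenotypeMatrix from a (sites x samples) genotype list."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = g.shape
    pos = np.asarray(pos if pos is not None else np.arange(1, n_sites + 1), dtype=np.int64)
    hap = None
    phased = None
    if haplotypes is not None:
        hap = np.asarray(haplotypes, dtype=np.int8)
        phased = np.ones(n_sites, dtype=bool)
    gm = GenotypeMatrix(
        sample_ids=[f"{sample_prefix}{i}" for i in range(n_samples)],
        chrom=np.array([chrom] * n_sites, dtype=object),
        pos=pos,
        genotypes=g,
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["T"] * n_sites, dtype=object),
        haplotypes=hap,
        phased=phased,
    )
    gm.validate()
    return gm


def popmap_for(gm, assignment):
    """assignment: list of population labels, one per sample."""
    return PopulationMap(sample_to_pop=dict(zip(gm.sample_ids, assignment)))


TOY_VCF = """##fileformat=VCFv4.2
##contig=<ID=chr1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\ts1\ts2
chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0|0\t0|1\t1|1
chr1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t0/0\t./.\t1/1
"""

HEADER_ONLY_VCF = """##fileformat=VCFv4.2
##contig=<ID=chr1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\ts1\ts2
"""

MULTIALLELIC_VCF = """##fileformat=VCFv4.2
##contig=<ID=chr1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\ts1\ts2
chr1\t100\t.\tA\tG,T\t.\tPASS\t.\tGT\t0/1\t0/2\t1/1
chr1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
chr1\t300\t.\tCA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
"""
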