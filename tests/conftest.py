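import numpy as np
import pytest

from medsweep.popgen import GenotypeMatrix, PopulationSplit


def make_gm(dosages, chrom="chr1", pos=None, sample_prefix="S"):
    """GenotypeMatrix from a plain nested list of dosages."""
    dos = np.asarray(dosages, dtype=np.int8)
    n_sites, n_samples = dos.shape
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 100
    return GenotypeMatrix(
        chrom=np.array([chrom] * n_sites, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["T"] * n_sites, dtype=object),
        dosages=dos,
        sample_ids=[f"{sample_prefix}{i}" for i in range(n_samples)],
    )


@pytest.fixture
def toy_vcf(tmp_path):
    """Five-record VCF: 3 biallelic SNPs, 1 indel, 1 triallelic site."""
    text = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC
chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1|1
chr1\t200\t.\tC\tG\t.\tPASS\t.\tGT\t0/0\t./.\t0/1
chr1\t300\t.\tAT\tA\t.\tPASS\t.\tGT\t0/0\t0/0\t0/0
chr1\t400\t.\tG\tA,C\t.\tPASS\t.\tGT\t0/0\t0/1\t0/2
chr1\t500\t.\tT\tC\t.\tPASS\t.\tGT\t1/1\t1/1\t1/1
"""
    path = tmp_path / "toy.vcf"
    path.write_text(text)
    return path


@pytest.fixture
def pop_split_4v4():
    return PopulationSplit(
        tuple(f"S{i}" for i in range(4)), tuple(f"S{i}" for i in range(4, 8))
    )


def random_site_pair(rng, n_min=2, n_max=6):
    """Random per-population dosage lists with random missingness; both
    populations keep at least two called individuals."""
    while True:
        pops = []
        for _ in range(2):
            n = int(rng.integers(n_min, n_max + 1))
            dos = rng.integers(0, 3, n).tolist()
            drop = rng.random(n) < 0.2
            dos = [d for d, x in zip(dos, drop) if not x]
            pops.append(dos)
        if min(len(p) for p in pops) >= 2:
            return pops[0], pops[1]
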