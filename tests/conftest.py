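import numpy as np
import pytest

from clonintro.core_io import GenotypeMatrix


def make_gm(dosage, chrom=None, pos=None, coded="derived", sample_ids=None):
    """Small genotype matrix from a dosage array (sites x samples)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_sites, n_samples = dosage.shape
    if chrom is None:
        chrom = ["chr1"] * n_sites
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 10
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n_samples)]
    return GenotypeMatrix(
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref_allele=np.asarray(["A"] * n_sites, dtype=object),
        alt_allele=np.asarray(["T"] * n_sites, dtype=object),
        dosage=dosage,
        sample_ids=list(sample_ids),
        coded=coded,
    )


TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc
chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
chr1\t200\t.\tC\tG,T\t.\tPASS\t.\tGT\t0/0\t0/1\t0/2
chr1\t300\t.\tA\tAT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
chr1\t400\t.\tG\tC\t.\tPASS\t.\tGT\t./.\t0/1\t1/1
chr1\t500\t.\tT\tA\t.\tPASS\t.\tGT\t1/1\t0/0\t0/1
"""


@pytest.fixture
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path


@pytest.fixture(scope="session")
def scenario_dataset():
    """One default-scenario dataset shared across read-only tests."""
    from clonintro.synthetic_data import ScenarioConfig, generate_dataset

    return generate_dataset(ScenarioConfig(seed=11))
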