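import numpy as np
import pytest

from primrose.io_preprocess import GenotypeMatrix
from primrose.synthdata import StudyDesign, generate_dataset

TINY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##contig=<ID=scaffold_7,length=5000>
##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">
##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">
##INFO=<ID=FS,Number=1,Type=Float,Description="Strand bias">
##INFO=<ID=DP,Number=1,Type=Float,Description="Depth">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
chr1\t101\t.\tA\tT\t50\t.\tQD=25.0;MQ=58.0;FS=1.2;DP=40\tGT:AD\t0/1:10,11\t1/1:0,20
chr1\t202\t.\tG\tC\t50\t.\tQD=30.0;MQ=60.0;FS=0.5;DP=38\tGT:AD\t0/0:18,0\t./.:.,.
chr1\t303\t.\tC\tG\t50\t.\tQD=28.0;MQ=59.0;FS=2.0;DP=41\tGT:AD\t0/1:9,10\t0/1:11,9
chr1\t404\t.\tT\tA,G\t50\t.\tQD=22.0;MQ=55.0;FS=3.0;DP=39\tGT:AD\t0/1:10,9,2\t0/2:11,1,8
scaffold_7\t55\t.\tA\tC\t50\t.\tQD=26.0;MQ=57.0;FS=1.0;DP=35\tGT:AD\t0/0:17,0\t0/1:8,9
"""


@pytest.fixture
def tiny_vcf(tmp_path):
    path = tmp_path / "tiny.vcf"
    path.write_text(TINY_VCF)
    return str(path)


def make_matrix(calls, positions=None, chrom="chr1", populations=None,
                samples=None):
    """Helper: a GenotypeMatrix from a dosage array (individuals x sites)."""
    calls = np.asarray(calls, dtype=np.int8)
    n_ind, n_sites = calls.shape
    pos = (np.asarray(positions, dtype=np.int64) if positions is not None
           else np.arange(n_sites, dtype=np.int64) * 100)
    return GenotypeMatrix(
        samples=samples or [f"s{i}" for i in range(n_ind)],
        chrom=np.array([chrom] * n_sites, dtype=object),
        pos=pos,
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["T"] * n_sites, dtype=object),
        calls=calls,
        populations=populations,
    )


@pytest.fixture(scope="session")
def founder_dataset():
    """A scaled-down serial-founder dataset shared across tests."""
    design = StudyDesign(n_chromosomes=4, chromosome_length=200_000)
    return generate_dataset(design, seed=20240917), design
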