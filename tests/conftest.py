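import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from panscan.haplotype import HaplotypeMatrix
from panscan.variants import VariantRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_matrix(rng, n_hap, n_site) -> HaplotypeMatrix:
    return HaplotypeMatrix(
        alleles=rng.integers(0, 2, size=(n_hap, n_site)),
        positions=np.cumsum(rng.integers(1, 100, size=n_site)),
    )


def make_record(
    chrom="1",
    pos=100,
    ref="A",
    alts=("G",),
    genotypes=None,
    gq=None,
    info=None,
    phased=False,
) -> VariantRecord:
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alts=alts,
        genotypes=genotypes or {},
        gq=gq,
        info=info or {},
        phased=phased,
    )


@pytest.fixture
def toy_vcf(tmp_path):
    """A small well-formed 2-record, 3-sample VCF on disk."""
    text = "\n".join(
        [
            "##fileformat=VCFv4.2",
            "##contig=<ID=1>",
            '##INFO=<ID=SUPP_VEC,Number=1,Type=String,Description="sv">',
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="GQ">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3",
            "1\t100\t.\tA\tG\t.\tPASS\tSUPP_VEC=101\tGT:GQ\t0|1:30\t1|1:24\t.|.:10",
            "1\t200\t.\tAC\tA\t.\t.\t.\tGT:GQ\t0|0:40\t1|0:41\t0|1:42",
        ]
    )
    path = tmp_path / "toy.vcf"
    path.write_text(text + "\n")
    return path
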