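import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from tas2rpop import GenotypeMatrix, SampleManifest, VariantRecord
from tas2rpop.annotation import Consequence


def matrix_from_haplotypes(haplotypes: np.ndarray, chrom="1", consequences=None) -> GenotypeMatrix:
    """Pack a sites x haplotypes 0/1 array into a GenotypeMatrix (haplotypes
    paired into diploids in order)."""
    haplotypes = np.asarray(haplotypes, dtype=np.int8)
    n_sites, n_hap = haplotypes.shape
    assert n_hap % 2 == 0
    samples = [f"S{i:03d}" for i in range(n_hap // 2)]
    dosages = haplotypes[:, 0::2] + haplotypes[:, 1::2]
    alt = haplotypes.sum(axis=1)
    hap_counts = np.stack([alt, np.full_like(alt, n_hap)], axis=1)
    variants = []
    for i in range(n_sites):
        v = VariantRecord(chrom=chrom, pos=i + 1, ref="A", alt="G",
                          alt_freq=float(alt[i]) / n_hap)
        if consequences is not None:
            v.consequence = consequences[i]
        variants.append(v)
    return GenotypeMatrix(variants=variants, dosages=dosages,
                          hap_counts=hap_counts, samples=samples)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_manifest():
    entries = [(f"S{i:03d}", "POP1" if i < 3 else "POP2", "SUPER1") for i in range(6)]
    return SampleManifest(entries)


@pytest.fixture
def tiny_vcf(tmp_path):
    """A 3-sample plain-text VCF with two biallelic SNPs, one multi-allelic
    record, one indel and one missing genotype."""
    text = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=7>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS000\tS001\tS002
7\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0|1\t0|0\t1|1
7\t150\t.\tC\tA,T\t.\tPASS\t.\tGT\t0|1\t1|2\t0|0
7\t200\trs2\tT\tC\t.\tPASS\t.\tGT\t0|0\t.|.\t0|1
7\t250\trs3\tG\tGA\t.\tPASS\t.\tGT\t0|1\t0|0\t0|0
"""
    path = tmp_path / "tiny.vcf"
    path.write_text(text)
    return path


@pytest.fixture
def tiny_panel_text():
    return "#sample\tpop\tsuper_pop\nS000\tYRI\tAFR\nS001\tYRI\tAFR\nS002\tCEU\tEUR\n"
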