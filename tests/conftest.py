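import numpy as np
import pytest

from bsamap.simcross import CausalLocus, Chromosome, GeneticMap

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=LG10,length=5000000>
##contig=<ID=LG03,length=5000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def write_vcf_text(path, rows, samples=("G", "Y", "G_pool", "Y_pool")):
    """Hand-build a small VCF; each row is a pre-formatted data line."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER.format(samples="\t".join(samples)))
        for row in rows:
            fh.write(row + "\n")
    return str(path)


def vcf_row(chrom, pos, ref, alt, *sample_fields):
    """One VCF line with GT:AD per sample, e.g. ('1/1', (0, 30))."""
    cells = [chrom, str(pos), ".", ref, alt, ".", ".", ".", "GT:AD"]
    for gt, (r, a) in sample_fields:
        cells.append(f"{gt}:{r},{a}")
    return "\t".join(cells)


@pytest.fixture
def small_map():
    """One 5 Mb / 25 cM chromosome, markers every 100 kb."""
    return GeneticMap.uniform([Chromosome("LG10", 5_000_000, 25.0)], 100_000)


@pytest.fixture
def two_chrom_map():
    """Causal chromosome plus an unlinked one, markers every 10 kb."""
    return GeneticMap.uniform(
        [Chromosome("LG10", 5_000_000, 25.0), Chromosome("LG03", 5_000_000, 25.0)], 10_000
    )


@pytest.fixture
def locus():
    return CausalLocus("LG10", 2_500_000)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
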