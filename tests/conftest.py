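import numpy as np
import pytest

from vcfhir import cohort_sim

MINIMAL_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">\n'
    '##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred Likelihoods">\n'
    "##contig=<ID=chr1>\n"
    "##contig=<ID=chr2>\n"
)


@pytest.fixture
def write_vcf(tmp_path):
    """Write a VCF file from data lines; returns the path."""

    def _write(lines, samples=("S1",), name="test.vcf", header=MINIMAL_VCF_HEADER):
        cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
        path = tmp_path / name
        path.write_text(header + cols + "\n" + "".join(l + "\n" for l in lines))
        return path

    return _write


@pytest.fixture(scope="session")
def line_fixture():
    """Two well-separated 1-D clusters {0,2} and {10,12}."""
    X = np.array([[0.0], [2.0], [10.0], [12.0]])
    labels = np.array([0, 0, 1, 1])
    return X, labels


@pytest.fixture(scope="session")
def small_cohort():
    return cohort_sim.simulate_cohort(50, seed=11)
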