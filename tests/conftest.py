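import numpy as np
import pytest

from ovis.simulate import ScenarioConfig, make_truth_bundle


@pytest.fixture(scope="session")
def bundle():
    """One default-scenario truth bundle shared across read-only tests."""
    return make_truth_bundle(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def toy_vcf(tmp_path_factory):
    """Hand-written VCF exercising dosage, DP masking, indels, multiallelics."""
    text = "\n".join([
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3",
        "chr1\t100\tv1\tA\tC\t.\t.\t.\tGT:DP\t0/1:10\t1/1:9\t0/0:8",
        "chr1\t200\tv2\tA\tC\t.\t.\t.\tGT:DP\t1/1:3\t0/1:10\t./.:9",
        "chr1\t300\tv3\tAT\tA\t.\t.\t.\tGT:DP\t0/1:10\t0/0:10\t0/0:10",
        "chr1\t400\tv4\tA\tC,G\t.\t.\t.\tGT:DP\t0/1:10\t0/2:10\t0/0:10",
        "chr1\t500\tv5\tG\tT\t.\t.\t.\tGT:DP\t0/0:10\t0/1:10\t1/1:10",
        "",
    ])
    path = tmp_path_factory.mktemp("vcf") / "toy.vcf"
    path.write_text(text)
    return path
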