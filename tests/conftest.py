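import textwrap
from pathlib import Path

import pytest

from charr import AlleleFrequencyMap, SiteGenotype, SiteKey

VCF_HEADER = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
    ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
    ##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
    """
)


def write_vcf_text(path: Path, rows, samples=("S1",), contigs=("1",)):
    """Write a minimal VCF. Each row: (chrom, pos, ref, alt, info, cells)."""
    with path.open("w") as fh:
        fh.write(VCF_HEADER)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for chrom, pos, ref, alt, info, cells in rows:
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t{info}\tGT:AD:DP:GQ\t" + "\t".join(cells) + "\n"
            )
    return path


def make_record(
    contig="1",
    pos=100,
    ref="A",
    alt="G",
    sample_id="S1",
    gt=2,
    ad_ref=0,
    ad_alt=30,
    dp=30,
    gq=60,
    multiallelic=False,
):
    return SiteGenotype(
        SiteKey(contig, pos, ref, alt), sample_id, gt, ad_ref, ad_alt, dp, gq, multiallelic
    )


@pytest.fixture
def af_half():
    """AF map answering q=0.5 (p=0.5) for any key it is given lazily."""

    class _Map(AlleleFrequencyMap):
        def alt_af(self, key):
            return 0.5

        def ref_af(self, key):
            return 0.5

    return _Map(source_label="constant-0.5")


@pytest.fixture
def tiny_vcf(tmp_path):
    """One sample, three biallelic SNVs, including the GQ=60/DP=51 record."""
    rows = [
        ("1", 100, "A", "G", "AF=0.35", ("1/1:3,48:51:60",)),
        ("1", 200, "C", "T", "AF=0.5", ("0/1:15,15:30:99",)),
        ("2", 300, "G", "A", "AF=0.8", ("0/0:28,0:28:80",)),
    ]
    return write_vcf_text(tmp_path / "tiny.vcf", rows, contigs=("1", "2"))
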