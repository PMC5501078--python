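import numpy as np
import pytest

from somavar.simulate import SimConfig, simulate_callsets, simulate_reference


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=7)


@pytest.fixture(scope="session")
def sim_reference(sim_config):
    return simulate_reference(sim_config)


@pytest.fixture(scope="session")
def sim_callsets(sim_config, sim_reference):
    return simulate_callsets(sim_config, sim_reference)


def write_text_vcf(path, records, sample="S1", contig="chr1", length=1_000_000):
    """Minimal hand-written caller VCF with AD/DP FORMAT fields."""
    header = (
        "##fileformat=VCFv4.2\n"
        f"##contig=<ID={contig},length={length}>\n"
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n'
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for chrom, pos, ref, alt, ad, dp in records:
            ad_str = ",".join(str(x) for x in ad)
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\tAD:DP\t{ad_str}:{dp}\n"
            )
    return str(path)


def revcomp_world(sequence, snvs):
    """Reverse-complement a single-contig reference and its SNVs (test oracle
    for strand invariance)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    L = len(sequence)
    rc_seq = "".join(comp[b] for b in reversed(sequence))
    rc_snvs = [
        (chrom, L - pos + 1, comp[ref], comp[alt]) for chrom, pos, ref, alt in snvs
    ]
    return rc_seq, rc_snvs
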