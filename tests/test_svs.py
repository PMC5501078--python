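"""Structural-variant filtering, insertion germline exclusion, gene context."""

import numpy as np
import pytest

from somavar.conservation import GeneModel
from somavar.simulate import SimConfig, simulate_svs
from somavar.svs import (
    ContigInsert,
    SplitRead,
    SVRecord,
    annotate_sv_genes,
    classify_insertions,
    filter_split_reads,
    kmer_coverage,
    quality_filter,
    read_sv_tsv,
    somatic_svs,
    write_sv_tsv,
)


def split_read(quals=(40,) * 100, parts=2, mapped=95):
    return SplitRead(
        read_id="r1",
        base_qualities=tuple(quals),
        alignment_parts=tuple(("chr1", i * 50, i * 50 + 50) for i in range(parts)),
        mapped_bases=mapped,
    )


class TestSplitReadFilter:
    def test_good_read_passes(self):
        assert filter_split_reads([split_read()]) == [split_read()]

    def test_94_quality_positions_fail(self):
        r = split_read(quals=(40,) * 94 + (10,) * 6)
        assert filter_split_reads([r]) == []

    def test_95_quality_positions_pass(self):
        r = split_read(quals=(35,) * 95 + (10,) * 5)
        assert filter_split_reads([r]) == [r]

    def test_three_alignment_parts_fail(self):
        assert filter_split_reads([split_read(parts=3)]) == []

    def test_91_mapped_bases_fail(self):
        assert filter_split_reads([split_read(mapped=91)]) == []
        assert filter_split_reads([split_read(mapped=92)]) != []


def contig(n_covered, length=100, cid="c1"):
    cov = np.zeros(length, dtype=int)
    cov[:n_covered] = 5
    return ContigInsert(cid, "A" * length, [("chr1", 1000)], cov)


class TestClassifyInsertions:
    def test_exact_90_percent_is_germline(self):
        df = classify_insertions([contig(90)])
        assert df.label.iloc[0] == "germline"

    def test_89_percent_is_somatic(self):
        df = classify_insertions([contig(89)])
        assert df.label.iloc[0] == "somatic"

    def test_planted_truth_recovered(self, sim_config, sim_reference):
        sv = simulate_svs(sim_config, sim_reference)
        df = classify_insertions(sv.contigs)
        truth = dict(zip(sv.truth.id, sv.truth.label))
        ins_truth = {k: v for k, v in truth.items() if k.startswith("contig")}
        got = dict(zip(df.contig_id, df.label))
        assert got == ins_truth

    def test_monotone_in_control_coverage(self):
        c = contig(85)
        before = classify_insertions([c]).label.iloc[0]
        c.control_coverage[85:91] = 3  # extra control reads
        after = classify_insertions([c]).label.iloc[0]
        assert (before, after) == ("somatic", "germline")

    def test_missing_coverage_is_error(self):
        with pytest.raises(ValueError):
            ContigInsert("c", "ACGT" * 10, control_coverage=np.zeros(5))


class TestKmerCoverage:
    def test_control_read_covers_its_kmers(self):
        rng = np.random.default_rng(0)
        contig_seq = "".join(rng.choice(list("ACGT"), size=120))
        read = contig_seq[10:60]
        cov = kmer_coverage(contig_seq, [read], k=31)
        assert (cov[10:41] >= 1).all()  # k-mer start positions span 10..29
        assert cov[:10].sum() == 0


def sv(sv_type="deletion", start=1000, end=2000, role="tumor", chrom="chr1",
       pairs=5, splits=5, **kw):
    return SVRecord(sv_type=sv_type, chrom1=chrom, start1=start, end1=end,
                    supporting_pairs=pairs, supporting_splits=splits,
                    sample_role=role, **kw)


def trans(p1, p2, role="tumor"):
    return SVRecord(sv_type="translocation", chrom1="chr1", start1=p1, end1=p1,
                    chrom2="chr2", start2=p2, end2=p2, supporting_pairs=5,
                    supporting_splits=5, sample_role=role)


class TestSomaticSvs:
    def test_identical_control_match_is_germline(self):
        somatic, _ = somatic_svs([sv()], [sv(role="normal")])
        assert somatic == []

    def test_translocation_without_control_match_is_somatic(self):
        somatic, counts = somatic_svs([trans(5000, 9000)],
                                      [trans(5000, 20000, role="normal")])
        assert len(somatic) == 1 and counts["translocation"] == 1

    def test_translocation_within_slop_excluded(self):
        somatic, _ = somatic_svs([trans(5000, 9000)],
                                 [trans(5080, 9090, role="normal")])
        assert somatic == []

    def test_partial_overlap_below_reciprocal_fraction_kept(self):
        tumor = sv(start=1000, end=2000)
        control = sv(start=1900, end=2900, role="normal")  # ~10% reciprocal
        somatic, _ = somatic_svs([tumor], [control])
        assert somatic == [tumor]

    def test_nonoverlapping_cluster_count(self):
        a = sv(start=100, end=200)
        b = sv(start=150, end=250)
        somatic, counts = somatic_svs([a, b], [])
        assert len(somatic) == 2
        assert counts["deletion"] == 1

    def test_quality_filter_threshold(self):
        weak = sv(pairs=1, splits=1)
        strong = sv(pairs=2, splits=1)
        assert quality_filter([weak, strong]) == [strong]

    def test_deletion_size_invariant(self):
        with pytest.raises(ValueError):
            sv(start=100, end=104)  # 5 bp deletion not allowed

    def test_planted_truth_recovered(self, sim_config, sim_reference):
        svsim = simulate_svs(sim_config, sim_reference)
        somatic, _ = somatic_svs(svsim.tumor_svs, svsim.control_svs)
        truth = svsim.truth[svsim.truth.kind == "sv"]
        expected = set(truth[truth.label == "somatic"].id)
        got = {f"{s.sv_type}:{s.chrom1}:{s.start1}" for s in somatic}
        assert got == expected

    def test_recall_robust_to_coordinate_jitter(self, sim_reference):
        rng = np.random.default_rng(31)
        recovered, total = 0, 0
        for seed in range(5):
            cfg = SimConfig(seed=seed)
            svsim = simulate_svs(cfg, sim_reference)
            jittered = []
            for c in svsim.control_svs:
                d1, d2 = int(rng.integers(-50, 51)), int(rng.integers(-50, 51))
                jittered.append(SVRecord(
                    sv_type=c.sv_type, chrom1=c.chrom1,
                    start1=max(1, c.start1 + d1), end1=c.end1 + d1,
                    chrom2=c.chrom2,
                    start2=None if c.start2 is None else max(1, c.start2 + d2),
                    end2=None if c.end2 is None else c.end2 + d2,
                    supporting_pairs=c.supporting_pairs,
                    supporting_splits=c.supporting_splits,
                    sample_role=c.sample_role))
            somatic, _ = somatic_svs(svsim.tumor_svs, jittered)
            truth = svsim.truth[svsim.truth.kind == "sv"]
            expected = set(truth[truth.label == "somatic"].id)
            got = {f"{s.sv_type}:{s.chrom1}:{s.start1}" for s in somatic}
            recovered += len(expected & got)
            total += len(expected)
        assert recovered / total >= 0.95

    def test_tsv_round_trip(self, tmp_path):
        records = [sv(), trans(100, 5000), sv("inversion", 3000, 4000)]
        path = tmp_path / "svs.tsv"
        write_sv_tsv(records, path)
        assert read_sv_tsv(path) == records


class TestGeneAnnotation:
    genes = [GeneModel("G1", "chr1", [(1000, 1100), (2000, 2100)])]

    def test_deletion_inside_intron(self):
        df = annotate_sv_genes([sv(start=1200, end=1400)], self.genes)
        assert df.region.iloc[0] == "intronic"
        assert df.genes.iloc[0] == "G1"

    def test_translocation_breakpoint_in_exon(self):
        t = trans(1050, 9000)
        df = annotate_sv_genes([t], self.genes)
        assert df.region.iloc[0] == "exonic"

    def test_intergenic_with_proximity_flag(self):
        df = annotate_sv_genes(
            [sv("insertion", 52_100, 52_100)], self.genes)
        row = df.iloc[0]
        assert row.region == "intergenic"
        assert row.distance == 50_000
        assert row.within_100kb

    def test_far_intergenic_not_flagged(self):
        genes = [GeneModel("G1", "chr1", [(1000, 1100)])]
        df = annotate_sv_genes([sv("insertion", 250_000, 250_000)], genes)
        assert not df.iloc[0].within_100kb
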