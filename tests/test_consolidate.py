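"""Cross-platform tiering, somatic extraction, and candidate filtering."""

import pandas as pd
import pytest

from somavar.consolidate import (
    CROSS_PLATFORM,
    SINGLE_TECHNOLOGY,
    SupportTable,
    build_report,
    classify_tier,
    extract_somatic,
    score_somatic,
    select_candidates,
)
from somavar.model import Annotation, ConsolidatedVariant, VariantCall
from somavar.simulate import SimConfig, simulate_callsets, simulate_reference


def call(platform, caller, maf, depth=100, role="tumor", pos=500):
    return VariantCall(
        chrom="chr1", pos=pos, ref="A", alt="T", sample_role=role,
        platform=platform, caller=caller, depth=depth,
        alt_reads=int(round(maf * depth)),
    )


def support_table(rows):
    return SupportTable(pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "sample_role",
                       "platform", "depth", "alt_reads"]))


class TestClassifyTier:
    def test_called_one_platform_supported_on_other(self):
        # DiBayes WES call at MAF 0.12; WGS pileup shows 7% -> cross-platform
        support = support_table([("chr1", 500, "A", "T", "tumor", "WGS", 100, 7)])
        tiers = classify_tier([call("WES", "dibayes", 0.12)], support=support)
        assert tiers["tumor"][0].tier == CROSS_PLATFORM

    def test_no_other_platform_support(self):
        tiers = classify_tier([call("WGS", "samtools", 0.30)])
        assert tiers["tumor"][0].tier == SINGLE_TECHNOLOGY

    def test_maf_exactly_at_threshold_fails(self):
        # "larger 5%" is strict: 0.05 on one platform is not enough
        support = support_table([("chr1", 500, "A", "T", "tumor", "WGS", 100, 5)])
        tiers = classify_tier([call("WES", "dibayes", 0.12)], support=support)
        assert tiers["tumor"][0].tier == SINGLE_TECHNOLOGY

    def test_roles_split_before_classification(self):
        calls = [call("WES", "gatk", 0.4, role="tumor"),
                 call("WES", "gatk", 0.4, role="normal")]
        tiers = classify_tier(calls)
        assert len(tiers["tumor"]) == 1 and len(tiers["normal"]) == 1

    def test_zero_depth_is_no_support(self):
        support = support_table([("chr1", 500, "A", "T", "tumor", "WGS", 0, 0)])
        tiers = classify_tier([call("WES", "dibayes", 0.12)], support=support)
        assert tiers["tumor"][0].tier == SINGLE_TECHNOLOGY

    def test_tiers_partition_the_union(self):
        calls = [call("WES", "gatk", 0.4, pos=p) for p in range(100, 140)]
        tiers = classify_tier(calls)
        keys = [v.key for v in tiers["tumor"]]
        assert len(keys) == len(set(keys)) == 40
        assert all(v.tier in (CROSS_PLATFORM, SINGLE_TECHNOLOGY)
                   for v in tiers["tumor"])


def consolidated(pos=500, **kw):
    base = dict(key=("chr1", pos, "A", "T"), tier=CROSS_PLATFORM)
    base.update(kw)
    return ConsolidatedVariant(**base)


class TestExtractSomatic:
    def test_clean_somatic(self):
        support = support_table([
            ("chr1", 500, "A", "T", "normal", "WGS", 10, 0),
            ("chr1", 500, "A", "T", "normal", "WES", 10, 0),
            ("chr1", 500, "A", "T", "tumor", "WGS", 10, 2),
            ("chr1", 500, "A", "T", "tumor", "WES", 10, 2),
        ])
        tumor = [consolidated(calls=(call("WGS", "samtools", 0.2, depth=10),))]
        out = extract_somatic(tumor, [], support)
        assert out[0].somatic is True

    def test_called_in_normal_is_germline(self):
        tumor = [consolidated(calls=(call("WGS", "samtools", 0.2),))]
        normal = [consolidated(calls=(call("WGS", "samtools", 0.4, role="normal"),))]
        out = extract_somatic(tumor, normal)
        assert out[0].somatic is False

    def test_normal_maf_above_bound_is_germline(self):
        support = support_table([("chr1", 500, "A", "T", "normal", "WGS", 100, 10)])
        tumor = [consolidated(calls=(call("WGS", "samtools", 0.2),))]
        assert extract_somatic(tumor, [], support)[0].somatic is False

    def test_low_coverage_platform_fails_min_reads(self):
        # tumor covered by only 2 reads in WES -> not reported somatic
        support = support_table([
            ("chr1", 500, "A", "T", "normal", "WGS", 10, 0),
            ("chr1", 500, "A", "T", "tumor", "WES", 2, 1),
        ])
        tumor = [consolidated(calls=(call("WGS", "samtools", 0.2, depth=10),))]
        assert extract_somatic(tumor, [], support)[0].somatic is False

    def test_missing_normal_data_is_unclassifiable(self):
        tumor = [consolidated(calls=(call("WGS", "samtools", 0.2),))]
        out = extract_somatic(tumor, [], support=None)
        assert out[0].somatic is None


class TestSelectCandidates:
    def _variant(self, fclass, damaging=False, conspos=False, gene="G1",
                 novel=True, somatic=True):
        return consolidated(
            somatic=somatic, novel=novel,
            annotation=Annotation(gene=gene, functional_class=fclass,
                                  damaging=damaging, conserved_position=conspos),
        )

    def test_stopgain_branch(self):
        v = self._variant("stopgain")
        assert select_candidates([v], set()) == [v]

    def test_damaging_in_conserved_gene_branch(self):
        v = self._variant("nonsynonymous", damaging=True)
        assert select_candidates([v], {"G1"}) == [v]

    def test_damaging_at_conserved_position(self):
        v = self._variant("nonsynonymous", damaging=True, conspos=True)
        assert select_candidates([v], set()) == [v]

    def test_damaging_but_nowhere_conserved_rejected(self):
        v = self._variant("nonsynonymous", damaging=True)
        assert select_candidates([v], set()) == []

    @pytest.mark.parametrize("kw", [dict(novel=False), dict(somatic=False)])
    def test_requires_novel_and_somatic(self, kw):
        v = self._variant("stopgain", **kw)
        assert select_candidates([v], set()) == []


class TestReportAndTruthRecovery:
    def test_empty_run_gives_zero_report(self):
        report = build_report([], [], [])
        assert report.cross_platform == report.somatic == report.candidate == 0

    def test_counts_monotone_along_chain(self, sim_callsets):
        support = SupportTable(sim_callsets.pileup)
        tiers = classify_tier(sim_callsets.all_calls(), support=support)
        flagged = extract_somatic(tiers["tumor"], tiers["normal"], support)
        report = build_report(sim_callsets.all_calls(), flagged)
        assert report.cross_platform >= report.somatic >= report.novel
        assert report.cross_platform + report.single_technology == len(flagged)

    def test_noise_free_truth_recovery(self, sim_callsets):
        support = SupportTable(sim_callsets.pileup)
        tiers = classify_tier(sim_callsets.all_calls(), support=support)
        flagged = extract_somatic(tiers["tumor"], tiers["normal"], support)
        precision, recall = score_somatic(
            flagged, sim_callsets.truth, sim_callsets.pileup)
        assert precision == 1.0 and recall == 1.0

    def test_platform_private_false_positives_stay_single_technology(self):
        cfg = SimConfig(seed=13, n_somatic_snvs=50, n_germline_snvs=100,
                        false_positives={("WES", "dibayes"): 20})
        ref = simulate_reference(cfg)
        cs = simulate_callsets(cfg, ref)
        fp_keys = {
            (r.chrom, r.pos, r.ref, r.alt)
            for r in cs.truth[cs.truth.label == "false_positive"]
            .itertuples(index=False)
        }
        assert len(fp_keys) == 20
        support = SupportTable(cs.pileup)
        tiers = classify_tier(cs.all_calls(), support=support)
        flagged = extract_somatic(tiers["tumor"], tiers["normal"], support)
        for v in flagged:
            if v.key in fp_keys:
                assert v.tier == SINGLE_TECHNOLOGY
                assert v.somatic is not True
        precision, _ = score_somatic(flagged, cs.truth, cs.pileup)
        assert precision == 1.0
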