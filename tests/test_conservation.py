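"""Exonic gene conservation score (ECS) and panel statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from somavar.conservation import (
    GeneModel,
    PanelStats,
    build_panel_stats,
    conserved_genes,
    ecs,
    ecs_table,
    panel_stats_from_counts,
    panel_stats_from_vcf,
    read_gene_bed,
)
from somavar.errors import PanelError
from somavar.simulate import SimConfig, simulate_panel


def single_gene_stats(v_g=4, l_tot=400, l_g=100, v_avg=3.0, s=2):
    return PanelStats(
        n_samples=s,
        per_gene_variants={"G1": v_g},
        gene_lengths={"G1": l_g},
        total_exonic_length=l_tot,
        avg_total_exonic_variants=v_avg,
    )


class TestEcsFormula:
    def test_worked_example(self):
        # hand arithmetic: 4 * 400 / (100 * 3 * 2) = 1600/600
        assert ecs(single_gene_stats(), "G1") == pytest.approx(1600 / 600)

    def test_average_density_gene_scores_one(self):
        # gene's per-bp rate equals the panel-wide average -> rate ratio 1
        stats = PanelStats(
            n_samples=10,
            per_gene_variants={"A": 30, "B": 70},
            gene_lengths={"A": 300, "B": 700},
            total_exonic_length=1000,
            avg_total_exonic_variants=10.0,
        )
        assert ecs(stats, "A") == pytest.approx(1.0)
        assert ecs(stats, "B") == pytest.approx(1.0)

    def test_zero_variants_maximally_conserved(self):
        assert ecs(single_gene_stats(v_g=0), "G1") == 0.0

    def test_zero_denominator_is_error(self):
        with pytest.raises(PanelError):
            ecs(single_gene_stats(v_avg=0.0), "G1")

    def test_conserved_threshold_is_strict(self):
        # ECS = 1 * l_tot / (100 * 100 * 2); l_tot chosen to hit 0.009 and 0.01
        below = single_gene_stats(v_g=1, l_tot=180, v_avg=100.0)  # 0.009
        at = single_gene_stats(v_g=1, l_tot=200, v_avg=100.0)  # exactly 0.01
        assert ecs(below, "G1") == pytest.approx(0.009)
        assert conserved_genes(below) == ["G1"]
        assert ecs(at, "G1") == pytest.approx(0.01)
        assert conserved_genes(at) == []

    def test_panel_duplication_invariance(self):
        base = single_gene_stats()
        doubled = single_gene_stats(v_g=8, s=4)
        assert ecs(base, "G1") == pytest.approx(ecs(doubled, "G1"))


def toy_genes():
    return [
        GeneModel("A", "chr1", [(101, 200)]),
        GeneModel("B", "chr1", [(301, 350), (401, 450)]),
    ]


class TestPanelStats:
    def test_counts_route_arithmetic(self):
        counts = pd.DataFrame(
            {"sample": ["s1", "s1", "s2", "s2"],
             "gene": ["A", "B", "A", "B"],
             "count": [3, 1, 1, 1]}
        )
        stats = panel_stats_from_counts(counts, toy_genes())
        assert stats.per_gene_variants == {"A": 4, "B": 2}
        assert stats.avg_total_exonic_variants == pytest.approx(3.0)
        assert stats.total_exonic_length == 200

    def test_length_weighted_mean_identity(self):
        rng = np.random.default_rng(3)
        genes = toy_genes()
        rows = []
        for s in range(5):
            for g in genes:
                rows.append((f"s{s}", g.gene, int(rng.integers(0, 20))))
        counts = pd.DataFrame(rows, columns=["sample", "gene", "count"])
        stats = panel_stats_from_counts(counts, genes)
        weighted = sum(
            ecs(stats, g.gene) * g.exonic_length for g in genes
        ) / stats.total_exonic_length
        assert weighted == pytest.approx(1.0, abs=1e-9)

    def test_empty_gene_model_is_error(self):
        with pytest.raises(PanelError):
            panel_stats_from_counts(
                pd.DataFrame({"sample": [], "gene": [], "count": []}), [])

    def _panel_vcf(self, tmp_path, rows):
        lines = [
            "##fileformat=VCFv4.2",
            "##contig=<ID=chr1,length=100000>",
            '##INFO=<ID=FCLASS,Number=1,Type=String,Description="class">',
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="genotype">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2",
        ]
        for pos, fclass, gt1, gt2 in rows:
            lines.append(
                f"chr1\t{pos}\t.\tA\tT\t.\t.\tFCLASS={fclass}\tGT\t{gt1}\t{gt2}"
            )
        path = tmp_path / "panel.vcf"
        path.write_text("\n".join(lines) + "\n")
        return str(path)

    def test_vcf_and_tsv_routes_agree(self, tmp_path):
        genes = toy_genes()
        vcf = self._panel_vcf(
            tmp_path,
            [(150, "nonsynonymous", "0/1", "0/1"),  # gene A, both samples
             (160, "nonsynonymous", "0/1", "0/0"),  # gene A, s1 only
             (320, "stopgain", "1/1", "0/1")],  # gene B, both
        )
        from_vcf = panel_stats_from_vcf(vcf, genes)
        counts = pd.DataFrame(
            {"sample": ["s1", "s1", "s2", "s2"],
             "gene": ["A", "B", "A", "B"],
             "count": [2, 1, 1, 1]}
        )
        from_tsv = panel_stats_from_counts(counts, genes)
        assert from_vcf.per_gene_variants == from_tsv.per_gene_variants
        assert from_vcf.n_samples == from_tsv.n_samples
        assert from_vcf.avg_total_exonic_variants == pytest.approx(
            from_tsv.avg_total_exonic_variants)

    def test_intronic_and_synonymous_variants_not_counted(self, tmp_path):
        genes = toy_genes()
        vcf = self._panel_vcf(
            tmp_path,
            [(250, "nonsynonymous", "0/1", "0/1"),  # between exons of no gene
             (150, "synonymous", "0/1", "0/1"),  # exonic but synonymous
             (150, "nonsynonymous", "0/1", "0/0")],
        )
        stats = panel_stats_from_vcf(vcf, genes)
        assert stats.per_gene_variants == {"A": 1, "B": 0}
        assert stats.n_outside_genes == 2


class TestBedReader:
    def test_bed_coordinates_converted(self, tmp_path):
        bed = tmp_path / "g.bed"
        bed.write_text("chr1\t100\t200\tA\nchr1\t300\t350\tB\nchr1\t400\t450\tB\n")
        genes = {g.gene: g for g in read_gene_bed(bed)}
        assert genes["A"].exons == [(101, 200)]
        assert genes["A"].exonic_length == 100
        assert genes["B"].exonic_length == 100


class TestSimulatedPanelRecovery:
    def test_ecs_ranks_genes_by_truth_multiplier(self, sim_reference):
        cfg = SimConfig(seed=21, panel_samples=300)
        panel = simulate_panel(cfg, sim_reference.genes)
        stats = panel_stats_from_counts(panel.counts, sim_reference.genes)
        table = ecs_table(stats)
        mult = table.gene.map(panel.multipliers)
        rho = spearmanr(mult, table.ecs).statistic
        assert rho > 0.9

    def test_low_multiplier_genes_flagged_conserved(self, sim_reference):
        mults = {g.gene: 1.0 for g in sim_reference.genes}
        dead = sim_reference.genes[0].gene
        mults[dead] = 0.0
        cfg = SimConfig(seed=22, panel_samples=200, gene_multipliers=mults)
        panel = simulate_panel(cfg, sim_reference.genes)
        stats = panel_stats_from_counts(panel.counts, sim_reference.genes)
        assert ecs(stats, dead) == 0.0
        assert dead in conserved_genes(stats)
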