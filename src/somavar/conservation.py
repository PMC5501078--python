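"""Exonic gene conservation score (ECS) from a population panel.

For gene g with V_g coding non-synonymous panel variants and exonic length
L_g, over a panel of S samples with mean per-sample exonic variant count
V_avg and total modeled exonic length L_tot:

    ECS(g) = (V_g * L_tot) / (L_g * V_avg * S)

i.e. the gene's exonic mutation rate divided by the panel-wide average exonic
mutation rate. Smaller ECS means stronger conservation; genes with
ECS < 0.01 are called conserved. When every panel variant lies inside a
modeled gene, the length-weighted mean of ECS over genes is exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd
import pysam

from .errors import PanelError

logger = logging.getLogger(__name__)

CONSERVED_THRESHOLD = 0.01
#: functional classes counted as coding non-synonymous for the panel
CODING_CLASSES = ("nonsynonymous", "stopgain", "frameshift_indel", "nonframeshift_indel")


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


@dataclass
class GeneModel:
    """A gene as a union of exon intervals (1-based inclusive, one contig)."""

    gene: str
    chrom: str
    exons: list[tuple[int, int]]  # merged, sorted

    def __post_init__(self) -> None:
        self.exons = _merge_intervals(self.exons)
        if self.exonic_length <= 0:
            raise ValueError(f"gene {self.gene} has zero exonic length")

    @property
    def exonic_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and any(s <= pos <= e for s, e in self.exons)


def read_gene_bed(path: Union[str, Path]) -> list[GeneModel]:
    """Read a gene model from BED (0-based half-open; column 4 = gene name).

    Rows sharing a gene name are merged into one exon union.
    """
    exons: dict[str, tuple[str, list[tuple[int, int]]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, gene = line.split("\t")[:4]
            entry = exons.setdefault(gene, (chrom, []))
            entry[1].append((int(start) + 1, int(end)))  # to 1-based inclusive
    return [GeneModel(gene=g, chrom=c, exons=iv) for g, (c, iv) in exons.items()]


@dataclass
class PanelStats:
    """Population-panel summary used by the ECS formula."""

    n_samples: int  # S
    per_gene_variants: dict[str, int]  # V_g
    gene_lengths: dict[str, int]  # L_g
    total_exonic_length: int  # L_tot (union over all modeled genes)
    avg_total_exonic_variants: float  # V_avg (mean per-sample count)
    n_outside_genes: int = 0  # panel variants not assigned to any gene
    per_gene_avg_variants: float = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.per_gene_variants)
        self.per_gene_avg_variants = (
            sum(self.per_gene_variants.values()) / n if n else 0.0
        )


def _total_exonic_length(genes: Sequence[GeneModel]) -> int:
    # union over all genes, so shared exonic bases are not double-counted
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).extend(g.exons)
    return sum(
        e - s + 1 for iv in by_chrom.values() for s, e in _merge_intervals(iv)
    )


def panel_stats_from_counts(
    counts: pd.DataFrame, genes: Sequence[GeneModel]
) -> PanelStats:
    """Build panel statistics from a pre-counted long table
    (columns: sample, gene, count)."""
    if not genes:
        raise PanelError("gene model is empty")
    required = {"sample", "gene", "count"}
    if not required.issubset(counts.columns):
        raise PanelError(f"count table needs columns {sorted(required)}")
    lengths = {g.gene: g.exonic_length for g in genes}
    unknown = set(counts["gene"]) - set(lengths)
    if unknown:
        raise PanelError(f"counts reference genes missing from the model: {sorted(unknown)[:5]}")
    per_gene = counts.groupby("gene")["count"].sum().to_dict()
    per_sample = counts.groupby("sample")["count"].sum()
    return PanelStats(
        n_samples=int(counts["sample"].nunique()),
        per_gene_variants={g.gene: int(per_gene.get(g.gene, 0)) for g in genes},
        gene_lengths=lengths,
        total_exonic_length=_total_exonic_length(genes),
        avg_total_exonic_variants=float(per_sample.mean()),
    )


def panel_stats_from_vcf(path: Union[str, Path], genes: Sequence[GeneModel]) -> PanelStats:
    """Build panel statistics from a multi-sample panel VCF.

    Only records whose INFO FCLASS is coding non-synonymous are used; a
    variant counts once per sample carrying a non-reference genotype, and is
    assigned to every gene whose exon union contains its position (variants
    in overlapping genes count for each). Variants outside all exons are
    ignored with a logged count but still contribute to the per-sample totals
    behind V_avg only if exonic — they are dropped entirely.
    """
    if not genes:
        raise PanelError("gene model is empty")
    per_gene = {g.gene: 0 for g in genes}
    per_sample: dict[str, int] = {}
    n_outside = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for s in samples:
            per_sample[s] = 0
        for rec in vcf:
            fclass = rec.info.get("FCLASS", "nonsynonymous")
            if fclass not in CODING_CLASSES:
                continue
            carriers = [
                s
                for s in samples
                if any(a not in (0, None) for a in (rec.samples[s].get("GT") or ()))
            ]
            if not carriers:
                continue
            hits = [g for g in genes if g.contains(rec.chrom, rec.pos)]
            if not hits:
                n_outside += len(carriers)
                continue
            for g in hits:
                per_gene[g.gene] += len(carriers)
            for s in carriers:
                per_sample[s] += 1
    if n_outside:
        logger.info("panel VCF: %d carrier-variants outside all modeled exons", n_outside)
    n_samples = len(samples)
    if n_samples == 0:
        raise PanelError("panel VCF has no samples")
    return PanelStats(
        n_samples=n_samples,
        per_gene_variants=per_gene,
        gene_lengths={g.gene: g.exonic_length for g in genes},
        total_exonic_length=_total_exonic_length(genes),
        avg_total_exonic_variants=sum(per_sample.values()) / n_samples,
        n_outside_genes=n_outside,
    )


def build_panel_stats(
    source: Union[str, Path, pd.DataFrame], genes: Sequence[GeneModel]
) -> PanelStats:
    """Dispatch on input kind: long count table (DataFrame or TSV path) or
    panel VCF path."""
    if isinstance(source, pd.DataFrame):
        return panel_stats_from_counts(source, genes)
    path = str(source)
    if path.endswith((".vcf", ".vcf.gz", ".bcf")):
        return panel_stats_from_vcf(path, genes)
    return panel_stats_from_counts(pd.read_csv(path, sep="\t"), genes)


def ecs(stats: PanelStats, gene: str, avg_over: str = "samples") -> float:
    """Exonic conservation score for one gene (see module docstring).

    ``avg_over='genes'`` is an alternative reading in which the average
    variant count is taken over genes instead of samples (kept behind this
    flag; the per-sample reading is the one under which ECS is a rate ratio
    with length-weighted mean 1).
    """
    if gene not in stats.per_gene_variants:
        raise PanelError(f"unknown gene {gene!r}")
    v_g = stats.per_gene_variants[gene]
    l_g = stats.gene_lengths[gene]
    if avg_over == "samples":
        v_avg, denom_s = stats.avg_total_exonic_variants, stats.n_samples
    elif avg_over == "genes":
        v_avg, denom_s = stats.per_gene_avg_variants, 1
    else:
        raise ValueError("avg_over must be 'samples' or 'genes'")
    if l_g <= 0 or v_avg <= 0 or denom_s <= 0:
        raise PanelError(
            f"degenerate ECS denominator for {gene}: L_g={l_g}, V_avg={v_avg}, S={denom_s}"
        )
    return (v_g * stats.total_exonic_length) / (l_g * v_avg * denom_s)


def ecs_table(stats: PanelStats, threshold: float = CONSERVED_THRESHOLD) -> pd.DataFrame:
    """Per-gene table: exonic length, panel variant count, ECS, conserved flag."""
    rows = [
        (
            g,
            stats.gene_lengths[g],
            stats.per_gene_variants[g],
            ecs(stats, g),
        )
        for g in sorted(stats.per_gene_variants)
    ]
    df = pd.DataFrame(rows, columns=["gene", "exonic_length", "panel_variants", "ecs"])
    df["conserved"] = df["ecs"] < threshold
    return df


def conserved_genes(stats: PanelStats, threshold: float = CONSERVED_THRESHOLD) -> list[str]:
    """Genes with ECS strictly below ``threshold``, sorted by name."""
    return sorted(g for g in stats.per_gene_variants if ecs(stats, g) < threshold)
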