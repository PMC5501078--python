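"""GO-term burden of damaging variants, filtered against a population panel.

A term is flagged enriched when the tumor's load (distinct affected genes, or
variant count) strictly exceeds the maximum load observed in any single panel
sample. The panel maxima are per-sample maxima, never pooled counts: pooling
would only inflate the reference and weaken every call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Tuple

import pandas as pd

#: a damaging-flagged variant observation: (gene, damaging)
GeneVariant = Tuple[str, bool]


@dataclass(frozen=True)
class TermStats:
    term: str
    tumor_gene_count: int
    tumor_variant_count: int
    panel_max_gene_count: int
    panel_max_variant_count: int
    enriched_by_genes: bool
    enriched_by_variants: bool


def term_load(
    variants: Iterable[GeneVariant], gene_terms: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Per-term damaging-variant load.

    ``variants`` yields (gene, damaging) pairs; non-damaging variants are
    ignored. A variant contributes to every term its gene maps to;
    ``gene_count`` counts distinct genes per term.
    """
    genes_per_term: dict[str, set[str]] = {}
    variants_per_term: dict[str, int] = {}
    for gene, damaging in variants:
        if not damaging or gene not in gene_terms:
            continue
        for term in gene_terms[gene]:
            genes_per_term.setdefault(term, set()).add(gene)
            variants_per_term[term] = variants_per_term.get(term, 0) + 1
    rows = [
        (term, len(genes_per_term[term]), variants_per_term[term])
        for term in sorted(variants_per_term)
    ]
    return pd.DataFrame(rows, columns=["term", "gene_count", "variant_count"])


def compare_to_panel(
    tumor_loads: pd.DataFrame, panel_loads: Mapping[str, pd.DataFrame]
) -> list[TermStats]:
    """Compare tumor per-term loads with the per-sample maxima of the panel.

    ``panel_loads`` maps panel sample id -> its :func:`term_load` table (built
    with the same gene->term map). A term absent from every panel sample has
    panel maxima 0.
    """
    panel_max_genes: dict[str, int] = {}
    panel_max_vars: dict[str, int] = {}
    for sample_df in panel_loads.values():
        for _, row in sample_df.iterrows():
            t = row["term"]
            panel_max_genes[t] = max(panel_max_genes.get(t, 0), int(row["gene_count"]))
            panel_max_vars[t] = max(panel_max_vars.get(t, 0), int(row["variant_count"]))
    out = []
    for _, row in tumor_loads.iterrows():
        t = row["term"]
        tg, tv = int(row["gene_count"]), int(row["variant_count"])
        pg, pv = panel_max_genes.get(t, 0), panel_max_vars.get(t, 0)
        out.append(
            TermStats(
                term=t,
                tumor_gene_count=tg,
                tumor_variant_count=tv,
                panel_max_gene_count=pg,
                panel_max_variant_count=pv,
                enriched_by_genes=tg > pg,
                enriched_by_variants=tv > pv,
            )
        )
    out.sort(key=lambda s: (-s.tumor_variant_count, s.term))
    return out


def term_stats_table(stats: Sequence[TermStats]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in stats])


def gene_terms_long(gene_terms: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    rows = [(g, t) for g, terms in gene_terms.items() for t in terms]
    return pd.DataFrame(rows, columns=["gene", "term"])


def panel_loads_from_counts(
    counts: pd.DataFrame, gene_terms: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Per-sample per-term loads from a long damaging-variant count table
    (columns: sample, gene, count). Vectorized equivalent of running
    :func:`term_load` over every panel sample."""
    merged = counts[counts["count"] > 0].merge(
        gene_terms_long(gene_terms), on="gene", how="inner"
    )
    if merged.empty:
        return pd.DataFrame(columns=["sample", "term", "gene_count", "variant_count"])
    agg = (
        merged.groupby(["sample", "term"])
        .agg(gene_count=("gene", "nunique"), variant_count=("count", "sum"))
        .reset_index()
    )
    return agg


def compare_to_panel_loads(
    tumor_loads: pd.DataFrame, panel_loads: pd.DataFrame
) -> list[TermStats]:
    """Like :func:`compare_to_panel` but taking the long per-sample load table
    produced by :func:`panel_loads_from_counts`."""
    if panel_loads.empty:
        maxima = pd.DataFrame(columns=["term", "gene_count", "variant_count"])
    else:
        maxima = (
            panel_loads.groupby("term")[["gene_count", "variant_count"]]
            .max()
            .reset_index()
        )
    max_genes = dict(zip(maxima["term"], maxima["gene_count"]))
    max_vars = dict(zip(maxima["term"], maxima["variant_count"]))
    out = []
    for _, row in tumor_loads.iterrows():
        t = row["term"]
        tg, tv = int(row["gene_count"]), int(row["variant_count"])
        pg, pv = int(max_genes.get(t, 0)), int(max_vars.get(t, 0))
        out.append(
            TermStats(
                term=t,
                tumor_gene_count=tg,
                tumor_variant_count=tv,
                panel_max_gene_count=pg,
                panel_max_variant_count=pv,
                enriched_by_genes=tg > pg,
                enriched_by_variants=tv > pv,
            )
        )
    out.sort(key=lambda s: (-s.tumor_variant_count, s.term))
    return out


def read_gene_term_map(path: str) -> dict[str, list[str]]:
    """Read a gene->term map TSV (columns: gene, term[, term_name])."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[str]] = {}
    for gene, term in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(str(gene), []).append(str(term))
    return out
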