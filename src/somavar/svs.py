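"""Structural-variant filtering and somatic classification.

Covers three concerns: split-read quality filtering (quality at >= 95
positions, <= 2 alignment parts, >= 92 mapped bases), germline exclusion of
de-novo-assembled insertion contigs (a contig covered by control reads at
>= 90% of its positions is germline), and somatic classification of interval
SVs / translocations against a matched control set (reciprocal overlap or
breakpoint proximity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .conservation import GeneModel

logger = logging.getLogger(__name__)

SV_TYPES = ("deletion", "inversion", "tandem_duplication", "translocation", "insertion")
INTERVAL_TYPES = ("deletion", "inversion", "tandem_duplication", "insertion")


@dataclass(frozen=True)
class SplitRead:
    """An unmapped read re-aligned in parts against the reference."""

    read_id: str
    base_qualities: tuple[int, ...]
    alignment_parts: tuple[tuple[str, int, int], ...]  # (target, start, end)
    mapped_bases: int


def filter_split_reads(
    reads: Iterable[SplitRead],
    q: int = 35,
    min_q_positions: int = 95,
    max_parts: int = 2,
    min_mapped: int = 92,
) -> list[SplitRead]:
    """Keep reads with >= ``min_q_positions`` bases at quality >= ``q``, at
    most ``max_parts`` alignment parts, and >= ``min_mapped`` mapped bases."""
    out = []
    for r in reads:
        n_good = sum(1 for bq in r.base_qualities if bq >= q)
        if (
            n_good >= min_q_positions
            and len(r.alignment_parts) <= max_parts
            and r.mapped_bases >= min_mapped
        ):
            out.append(r)
    return out


@dataclass
class ContigInsert:
    """A tumor-assembled contig that may represent a novel insertion."""

    contig_id: str
    sequence: str
    putative_insert_positions: list[tuple[str, int]] = field(default_factory=list)
    control_coverage: Optional[np.ndarray] = None  # per-position control depth

    def __post_init__(self) -> None:
        if self.control_coverage is not None:
            self.control_coverage = np.asarray(self.control_coverage)
            if len(self.control_coverage) != len(self.sequence):
                raise ValueError(
                    f"contig {self.contig_id}: coverage length "
                    f"{len(self.control_coverage)} != contig length {len(self.sequence)}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def covered_fraction(self) -> float:
        if self.control_coverage is None:
            raise ValueError(f"contig {self.contig_id}: control coverage not populated")
        return float(np.mean(self.control_coverage >= 1))


def classify_insertions(
    contigs: Sequence[ContigInsert],
    germline_coverage_fraction: float = 0.90,
    genes: Optional[Sequence[GeneModel]] = None,
    proximity_bp: int = 100_000,
) -> pd.DataFrame:
    """Label insertion contigs germline/somatic by control-read coverage.

    A contig is germline when control reads cover >= ``germline_coverage_fraction``
    of its positions (inclusive boundary: 90/100 covered positions is
    germline). Somatic candidates keep their putative insert positions; when a
    gene model is given, the nearest gene and its distance are reported along
    with a flag for distance < ``proximity_bp``.
    """
    rows = []
    for contig in contigs:
        frac = contig.covered_fraction
        label = "germline" if frac >= germline_coverage_fraction else "somatic"
        nearest_gene, distance, region = "", np.nan, ""
        if label == "somatic" and genes and contig.putative_insert_positions:
            chrom, pos = contig.putative_insert_positions[0]
            region, hit_genes, distance = locate_position(chrom, pos, genes)
            nearest_gene = hit_genes[0] if hit_genes else ""
        rows.append(
            (
                contig.contig_id,
                contig.length,
                frac,
                label,
                nearest_gene,
                distance,
                region,
                bool(distance < proximity_bp) if not np.isnan(distance) else False,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "contig_id",
            "length",
            "covered_fraction",
            "label",
            "nearest_gene",
            "gene_distance",
            "region",
            "within_100kb",
        ],
    )


def kmer_coverage(contig: str, reads: Iterable[str], k: int = 31) -> np.ndarray:
    """Exact k-mer coverage of a contig by a read set (both strands).

    A deliberately simple stand-in for re-aligning control reads against
    tumor contigs in synthetic end-to-end tests; not a BLAT replacement.
    """
    comp = str.maketrans("ACGT", "TGCA")
    contig = contig.upper()
    index: dict[str, list[int]] = {}
    for i in range(len(contig) - k + 1):
        index.setdefault(contig[i : i + k], []).append(i)
    cov = np.zeros(len(contig), dtype=int)
    for read in reads:
        read = read.upper()
        rc = read.translate(comp)[::-1]
        for seq in (read, rc):
            for j in range(len(seq) - k + 1):
                for i in index.get(seq[j : j + k], ()):
                    cov[i : i + k] += 1
    return cov


@dataclass
class SVRecord:
    """One structural-variant call (interval SV or translocation)."""

    sv_type: str
    chrom1: str
    start1: int
    end1: int
    chrom2: Optional[str] = None  # translocations only
    start2: Optional[int] = None
    end2: Optional[int] = None
    supporting_pairs: int = 0
    supporting_splits: int = 0
    sample_role: str = "tumor"

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        if self.sv_type == "translocation":
            if self.chrom2 is None or self.chrom2 == self.chrom1:
                raise ValueError("translocation loci must be on different chromosomes")
        elif self.sv_type == "deletion" and self.size <= 5:
            raise ValueError("only deletions larger than five basepairs are kept")

    @property
    def size(self) -> int:
        return self.end1 - self.start1 + 1

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chrom1, self.start1, self.end1)


def quality_filter(svs: Iterable[SVRecord], min_support: int = 3) -> list[SVRecord]:
    """Keep SVs with combined read-pair + split-read support >= ``min_support``.

    The per-tool thresholds of the original callers are not part of this
    package; the default of 3 supporting observations is a parameter.
    """
    return [s for s in svs if s.supporting_pairs + s.supporting_splits >= min_support]


def _reciprocal_overlap(a: SVRecord, b: SVRecord, frac: float) -> bool:
    if a.chrom1 != b.chrom1:
        return False
    inter = min(a.end1, b.end1) - max(a.start1, b.start1) + 1
    if inter <= 0:
        return False
    return inter / a.size >= frac and inter / b.size >= frac


def _translocation_match(a: SVRecord, b: SVRecord, slop: int) -> bool:
    def near(c1, p1, c2, p2):
        return c1 == c2 and abs(p1 - p2) <= slop

    fwd = near(a.chrom1, a.start1, b.chrom1, b.start1) and near(
        a.chrom2, a.start2, b.chrom2, b.start2
    )
    rev = near(a.chrom1, a.start1, b.chrom2, b.start2) and near(
        a.chrom2, a.start2, b.chrom1, b.start1
    )
    return fwd or rev


def _matches(a: SVRecord, b: SVRecord, overlap: float, slop: int) -> bool:
    if a.sv_type != b.sv_type:
        return False
    if a.sv_type == "translocation":
        return _translocation_match(a, b, slop)
    if a.sv_type == "insertion":
        return a.chrom1 == b.chrom1 and abs(a.start1 - b.start1) <= slop
    return _reciprocal_overlap(a, b, overlap)


def _cluster_count(svs: Sequence[SVRecord], slop: int) -> int:
    """Number of clusters of mutually overlapping same-type SVs."""
    if not svs:
        return 0
    n = len(svs)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = svs[i], svs[j]
            if a.sv_type == "translocation":
                linked = _translocation_match(a, b, slop)
            else:
                linked = (
                    a.chrom1 == b.chrom1
                    and min(a.end1, b.end1) - max(a.start1, b.start1) >= 0
                )
            if linked:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})


def somatic_svs(
    tumor: Sequence[SVRecord],
    control: Sequence[SVRecord],
    overlap: float = 0.5,
    breakpoint_slop: int = 100,
) -> tuple[list[SVRecord], dict[str, int]]:
    """Somatically classify tumor SVs against the matched control.

    A tumor SV is somatic iff no control SV of the same type matches it
    (interval types: reciprocal overlap >= ``overlap``; translocations: both
    breakpoints within ``breakpoint_slop``). Also returns, per SV type, the
    "non-overlapping" count: mutually overlapping somatic SVs of one type are
    merged into clusters and clusters are counted.
    """
    somatic = [
        t
        for t in tumor
        if not any(_matches(t, c, overlap, breakpoint_slop) for c in control)
    ]
    counts: dict[str, int] = {}
    for sv_type in SV_TYPES:
        of_type = [s for s in somatic if s.sv_type == sv_type]
        if of_type:
            counts[sv_type] = _cluster_count(of_type, breakpoint_slop)
    return somatic, counts


def locate_position(
    chrom: str, pos: int, genes: Sequence[GeneModel]
) -> tuple[str, list[str], float]:
    """Classify a locus as exonic/intronic/intergenic against a gene model.

    Returns (region, genes hit or nearest, distance). Distance is 0 inside a
    gene and the gap to the nearest gene span otherwise (inf with no gene on
    the chromosome).
    """
    exonic = [g.gene for g in genes if g.contains(chrom, pos)]
    if exonic:
        return "exonic", exonic, 0.0
    intronic = [
        g.gene
        for g in genes
        if g.chrom == chrom and g.span[0] <= pos <= g.span[1]
    ]
    if intronic:
        return "intronic", intronic, 0.0
    best_gene, best_dist = "", float("inf")
    for g in genes:
        if g.chrom != chrom:
            continue
        lo, hi = g.span
        dist = lo - pos if pos < lo else pos - hi
        if dist < best_dist:
            best_gene, best_dist = g.gene, float(dist)
    return "intergenic", [best_gene] if best_gene else [], best_dist


def annotate_sv_genes(
    svs: Sequence[SVRecord],
    genes: Sequence[GeneModel],
    proximity_bp: int = 100_000,
) -> pd.DataFrame:
    """Annotate SVs with gene context.

    Exonic if any breakpoint/interval intersects an exon; else intronic if
    inside a gene; else intergenic with the distance to the nearest gene and
    a < 100 kb proximity flag.
    """
    rows = []
    for sv in svs:
        if sv.sv_type == "translocation":
            loci = [(sv.chrom1, sv.start1), (sv.chrom2, sv.start2)]
        else:
            loci = [(sv.chrom1, p) for p in range(sv.start1, sv.end1 + 1, max(1, sv.size - 1))]
            # interval SVs: exon intersection must consider the whole interval
            hit_exonic = [
                g.gene
                for g in genes
                if g.chrom == sv.chrom1
                and any(s <= sv.end1 and e >= sv.start1 for s, e in g.exons)
            ]
            if hit_exonic:
                rows.append(
                    (_sv_id(sv), sv.sv_type, "exonic", ",".join(sorted(set(hit_exonic))), 0.0, True)
                )
                continue
        results = [locate_position(c, p, genes) for c, p in loci]
        if any(r[0] == "exonic" for r in results):
            hit = sorted({g for r in results if r[0] == "exonic" for g in r[1]})
            rows.append((_sv_id(sv), sv.sv_type, "exonic", ",".join(hit), 0.0, True))
        elif any(r[0] == "intronic" for r in results):
            hit = sorted({g for r in results if r[0] == "intronic" for g in r[1]})
            rows.append((_sv_id(sv), sv.sv_type, "intronic", ",".join(hit), 0.0, True))
        else:
            dist = min(r[2] for r in results)
            nearest = sorted({g for r in results if r[2] == dist for g in r[1]})
            rows.append(
                (
                    _sv_id(sv),
                    sv.sv_type,
                    "intergenic",
                    ",".join(nearest),
                    dist,
                    bool(dist < proximity_bp),
                )
            )
    return pd.DataFrame(
        rows, columns=["sv_id", "sv_type", "region", "genes", "distance", "within_100kb"]
    )


def _sv_id(sv: SVRecord) -> str:
    if sv.sv_type == "translocation":
        return f"{sv.sv_type}:{sv.chrom1}:{sv.start1}|{sv.chrom2}:{sv.start2}"
    return f"{sv.sv_type}:{sv.chrom1}:{sv.start1}-{sv.end1}"


# --- BEDPE-like TSV I/O -----------------------------------------------------

_SV_COLUMNS = [
    "sv_type",
    "chrom1",
    "start1",
    "end1",
    "chrom2",
    "start2",
    "end2",
    "supporting_pairs",
    "supporting_splits",
    "sample_role",
]


def write_sv_tsv(svs: Sequence[SVRecord], path: Union[str, Path]) -> None:
    rows = []
    for s in svs:
        rows.append(
            (
                s.sv_type,
                s.chrom1,
                s.start1,
                s.end1,
                s.chrom2 or ".",
                s.start2 if s.start2 is not None else ".",
                s.end2 if s.end2 is not None else ".",
                s.supporting_pairs,
                s.supporting_splits,
                s.sample_role,
            )
        )
    pd.DataFrame(rows, columns=_SV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_sv_tsv(path: Union[str, Path]) -> list[SVRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom1": str, "chrom2": str})
    out = []
    for _, r in df.iterrows():
        trans = r["sv_type"] == "translocation"
        out.append(
            SVRecord(
                sv_type=r["sv_type"],
                chrom1=str(r["chrom1"]),
                start1=int(r["start1"]),
                end1=int(r["end1"]),
                chrom2=str(r["chrom2"]) if trans else None,
                start2=int(r["start2"]) if trans else None,
                end2=int(r["end2"]) if trans else None,
                supporting_pairs=int(r["supporting_pairs"]),
                supporting_splits=int(r["supporting_splits"]),
                sample_role=str(r["sample_role"]),
            )
        )
    return out


def read_coverage_tsv(path: Union[str, Path]) -> dict[str, np.ndarray]:
    """Read a per-position contig coverage TSV (contig_id, pos, depth)."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, np.ndarray] = {}
    for contig_id, grp in df.groupby("contig_id"):
        grp = grp.sort_values("pos")
        cov = np.zeros(int(grp["pos"].max()), dtype=int)
        cov[grp["pos"].to_numpy() - 1] = grp["depth"].to_numpy()
        out[str(contig_id)] = cov
    return out


def write_coverage_tsv(coverage: dict[str, np.ndarray], path: Union[str, Path]) -> None:
    rows = [
        (cid, i + 1, int(d))
        for cid, cov in coverage.items()
        for i, d in enumerate(cov)
    ]
    pd.DataFrame(rows, columns=["contig_id", "pos", "depth"]).to_csv(
        path, sep="\t", index=False
    )
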