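"""Cross-platform / cross-caller variant consolidation and somatic filtering.

Tier rule: a variant is *cross-platform* when it was called by at least one
caller on either platform AND its mutant allele fraction exceeds the
threshold (default 5%, strict) on BOTH platforms within the same sample role.
MAF evidence for a platform that did not call the variant can come from a
supplementary pileup-support table (the raw-data check of the other
technology). Everything else is *single technology*.

Somatic rule: present in the tumor, absent from every matched-normal call
set, normal MAF at the position at most ``normal_maf_max``, and covered by at
least ``min_reads`` in each platform data set where coverage is known. A
variant with no matched-normal evidence at all is unclassifiable, never
somatic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .model import (
    ConsolidatedVariant,
    PLATFORMS,
    VariantCall,
    VariantKey,
    trim_variant,
)

MAF_THRESHOLD = 0.05
NORMAL_MAF_MAX = 0.05
MIN_READS = 3

CROSS_PLATFORM = "cross_platform"
SINGLE_TECHNOLOGY = "single_technology"


class SupportTable:
    """Pileup read support at variant positions, per sample role and platform.

    Built from a TSV/DataFrame with columns chrom, pos, ref, alt, sample_role,
    platform, depth, alt_reads (ref/alt optional; when present the lookup is
    allele-specific with a positional fallback).
    """

    def __init__(self, table: Union[str, Path, pd.DataFrame]):
        if not isinstance(table, pd.DataFrame):
            table = pd.read_csv(table, sep="\t", dtype={"chrom": str})
        self._allele: dict[tuple, tuple[int, int]] = {}
        self._pos: dict[tuple, tuple[int, int]] = {}
        has_alleles = "ref" in table.columns and "alt" in table.columns
        for row in table.itertuples(index=False):
            depth, alt_reads = int(row.depth), int(row.alt_reads)
            base = (str(row.chrom), int(row.pos), row.sample_role, row.platform)
            if has_alleles:
                pos, ref, alt = trim_variant(int(row.pos), str(row.ref), str(row.alt))
                self._allele[(str(row.chrom), pos, ref, alt, row.sample_role, row.platform)] = (
                    depth,
                    alt_reads,
                )
            prev = self._pos.get(base)
            if prev is None or alt_reads > prev[1]:
                self._pos[base] = (depth, alt_reads)

    def lookup(
        self, key: VariantKey, sample_role: str, platform: str
    ) -> Optional[tuple[int, int]]:
        chrom, pos, ref, alt = key
        hit = self._allele.get((chrom, pos, ref, alt, sample_role, platform))
        if hit is not None:
            return hit
        return self._pos.get((chrom, pos, sample_role, platform))

    def maf(self, key: VariantKey, sample_role: str, platform: str) -> Optional[float]:
        hit = self.lookup(key, sample_role, platform)
        if hit is None or hit[0] == 0:
            return None
        return hit[1] / hit[0]

    def depth(self, key: VariantKey, sample_role: str, platform: str) -> Optional[int]:
        hit = self.lookup(key, sample_role, platform)
        return hit[0] if hit is not None else None

    def has_normal_data(self, key: VariantKey) -> bool:
        return any(
            self.lookup(key, "normal", platform) is not None for platform in PLATFORMS
        )


def classify_tier(
    calls: Iterable[VariantCall],
    maf_threshold: float = MAF_THRESHOLD,
    support: Optional[SupportTable] = None,
) -> dict[str, list[ConsolidatedVariant]]:
    """Merge calls by variant key and assign evidence tiers.

    Calls are split by sample role before classification; the result maps
    role -> consolidated variants (sorted by key). The MAF on a platform is
    the best over that platform's calls, falling back to the pileup-support
    table for a platform without a call. The threshold is strict ("larger
    5%"): a MAF exactly at the threshold fails.
    """
    grouped: dict[tuple[str, VariantKey], list[VariantCall]] = {}
    for call in calls:
        grouped.setdefault((call.sample_role, call.key), []).append(call)

    out: dict[str, list[ConsolidatedVariant]] = {}
    for (role, key), group in sorted(grouped.items()):
        supported = 0
        for platform in PLATFORMS:
            mafs = [c.maf for c in group if c.platform == platform and c.maf is not None]
            maf = max(mafs) if mafs else None
            if maf is None and support is not None:
                maf = support.maf(key, role, platform)
            if maf is not None and maf > maf_threshold:
                supported += 1
        tier = CROSS_PLATFORM if supported == len(PLATFORMS) else SINGLE_TECHNOLOGY
        out.setdefault(role, []).append(
            ConsolidatedVariant(key=key, calls=tuple(group), tier=tier)
        )
    return out


def extract_somatic(
    tumor: Sequence[ConsolidatedVariant],
    normal: Sequence[ConsolidatedVariant],
    support: Optional[SupportTable] = None,
    normal_maf_max: float = NORMAL_MAF_MAX,
    min_reads: int = MIN_READS,
) -> list[ConsolidatedVariant]:
    """Flag tumor variants somatic / non-somatic / unclassifiable (None)."""
    normal_keys = {v.key for v in normal}
    out = []
    for v in tumor:
        out.append(
            replace(
                v,
                somatic=_somatic_status(
                    v, normal_keys, support, normal_maf_max, min_reads
                ),
            )
        )
    return out


def _somatic_status(
    v: ConsolidatedVariant,
    normal_keys: set[VariantKey],
    support: Optional[SupportTable],
    normal_maf_max: float,
    min_reads: int,
) -> Optional[bool]:
    if v.key in normal_keys:
        return False  # present in the matched normal: germline
    # normal contamination bound needs matched-normal read evidence
    if support is None or not support.has_normal_data(v.key):
        return None  # unclassifiable, never somatic
    for platform in PLATFORMS:
        maf = support.maf(v.key, "normal", platform)
        if maf is not None and maf > normal_maf_max:
            return False
    # tumor coverage: >= min_reads in each platform data set where known
    for platform in PLATFORMS:
        depth = v.platform_depth(platform)
        if depth is None and support is not None:
            depth = support.depth(v.key, "tumor", platform)
        if depth is not None and depth < min_reads:
            return False
    return True


CANDIDATE_CLASSES = ("nonsynonymous", "stopgain")


def select_candidates(
    variants: Sequence[ConsolidatedVariant], ecs_conserved: set[str]
) -> list[ConsolidatedVariant]:
    """Novel somatic exonic candidates: stopgain, or damaging at a conserved
    position / in a conserved gene (``ecs_conserved``)."""
    out = []
    for v in variants:
        ann = v.annotation
        if not (v.novel and v.somatic and ann.functional_class in CANDIDATE_CLASSES):
            continue
        if ann.functional_class == "stopgain" or (
            ann.damaging and (ann.conserved_position or ann.gene in ecs_conserved)
        ):
            out.append(v)
    return out


@dataclass
class FilterReport:
    """Per-stage variant counts along the consolidation / filter chain."""

    raw_per_caller: dict[str, int]
    union_per_platform: dict[str, int]
    cross_platform: int
    single_technology: int
    somatic: int  # somatic among cross-platform variants
    novel: int  # novel among those
    candidate: int

    def to_frame(self) -> pd.DataFrame:
        rows = [(f"raw:{k}", v) for k, v in sorted(self.raw_per_caller.items())]
        rows += [(f"union:{k}", v) for k, v in sorted(self.union_per_platform.items())]
        rows += [
            ("cross_platform", self.cross_platform),
            ("single_technology", self.single_technology),
            ("somatic", self.somatic),
            ("novel", self.novel),
            ("candidate", self.candidate),
        ]
        return pd.DataFrame(rows, columns=["stage", "count"])

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_report(
    calls: Sequence[VariantCall],
    consolidated_tumor: Sequence[ConsolidatedVariant],
    candidates: Sequence[ConsolidatedVariant] = (),
) -> FilterReport:
    """Summarize counts at each stage (tumor-role chain)."""
    raw: dict[str, int] = {}
    union_keys: dict[str, set] = {}
    for c in calls:
        if c.sample_role != "tumor":
            continue
        label = f"{c.platform}:{c.caller}"
        raw[label] = raw.get(label, 0) + 1
        union_keys.setdefault(c.platform, set()).add(c.key)
    cross = [v for v in consolidated_tumor if v.tier == CROSS_PLATFORM]
    single = [v for v in consolidated_tumor if v.tier == SINGLE_TECHNOLOGY]
    somatic = [v for v in cross if v.somatic]
    novel = [v for v in somatic if v.novel]
    return FilterReport(
        raw_per_caller=raw,
        union_per_platform={k: len(v) for k, v in union_keys.items()},
        cross_platform=len(cross),
        single_technology=len(single),
        somatic=len(somatic),
        novel=len(novel),
        candidate=len(candidates),
    )


def score_somatic(
    consolidated_tumor: Sequence[ConsolidatedVariant],
    truth: pd.DataFrame,
    pileup: pd.DataFrame,
    maf_threshold: float = MAF_THRESHOLD,
    min_reads: int = MIN_READS,
) -> tuple[float, float]:
    """Somatic precision/recall of the pipeline against a simulation truth table.

    Precision is unconditional over reported cross-platform somatic variants.
    Recall is over truth somatic variants *eligible* under the stated filters:
    emitted tumor read support with MAF strictly above the threshold on both
    platforms and depth >= min_reads (the cross-platform filter is part of
    the pipeline's definition, so a truth variant it is required to drop does
    not count against recall).
    """
    predicted = {
        v.key for v in consolidated_tumor if v.tier == CROSS_PLATFORM and v.somatic
    }
    somatic_truth = truth[truth["label"] == "somatic"]
    tumor_pileup = pileup[pileup["sample_role"] == "tumor"]
    eligible = set()
    for row in somatic_truth.itertuples(index=False):
        key = (str(row.chrom), int(row.pos), row.ref, row.alt)
        rows = tumor_pileup[
            (tumor_pileup["chrom"] == row.chrom) & (tumor_pileup["pos"] == row.pos)
            & (tumor_pileup["alt"] == row.alt)
        ]
        ok = len(rows) > 0
        for platform in PLATFORMS:
            prow = rows[rows["platform"] == platform]
            if prow.empty:
                ok = False
                break
            depth = int(prow["depth"].iloc[0])
            alt_reads = int(prow["alt_reads"].iloc[0])
            if depth < min_reads or depth == 0 or alt_reads / depth <= maf_threshold:
                ok = False
                break
        if ok:
            eligible.add(key)
    truth_keys = {
        (str(r.chrom), int(r.pos), r.ref, r.alt)
        for r in somatic_truth.itertuples(index=False)
    }
    tp = len(predicted & truth_keys)
    precision = tp / len(predicted) if predicted else 1.0
    recall = (
        len(predicted & eligible) / len(eligible) if eligible else 1.0
    )
    return precision, recall
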