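"""Domain types and VCF readers/writers for variant-level data.

Coordinates are 1-based inclusive (VCF convention) everywhere; BED inputs
(0-based half-open) are converted at the reader boundary. Indels are trimmed
to minimal representation before keying so that callers reporting different
representations of the same event merge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pysam

from .errors import MissingDepthError, VcfParseError

SAMPLE_ROLES = ("tumor", "normal")
PLATFORMS = ("WES", "WGS")

FUNCTIONAL_CLASSES = (
    "synonymous",
    "nonsynonymous",
    "stopgain",
    "frameshift_indel",
    "nonframeshift_indel",
    "intronic",
    "intergenic",
    "other",
)

#: variant key: (chrom, pos, ref, alt) after minimal-representation trimming
VariantKey = tuple[str, int, str, str]


def trim_variant(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Reduce an allele pair to minimal representation.

    Shared trailing bases are removed first, then shared leading bases (the
    position advances with each leading base removed). SNVs pass through
    unchanged; caller-dependent padded indel representations collapse to a
    single key.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass(frozen=True)
class VariantCall:
    """One caller's observation of one ALT allele in one sample on one platform."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    sample_role: str  # tumor | normal
    platform: str  # WES | WGS
    caller: str
    depth: int
    alt_reads: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.alt == self.ref:
            raise ValueError("alt allele equals ref allele")
        if self.sample_role not in SAMPLE_ROLES:
            raise ValueError(f"sample_role must be one of {SAMPLE_ROLES}")
        if self.platform not in PLATFORMS:
            raise ValueError(f"platform must be one of {PLATFORMS}")
        if not 0 <= self.alt_reads <= self.depth:
            raise ValueError("require 0 <= alt_reads <= depth")

    @property
    def maf(self) -> Optional[float]:
        """Mutant allele fraction; None (no support) when depth is zero."""
        if self.depth == 0:
            return None
        return self.alt_reads / self.depth

    @property
    def key(self) -> VariantKey:
        return (self.chrom, *trim_variant(self.pos, self.ref, self.alt))

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class Annotation:
    """Functional annotation flags attached to a consolidated variant."""

    gene: str = ""
    functional_class: str = "other"
    damaging: bool = False
    conserved_position: bool = False
    known_dbsnp: bool = False
    cancer_census: bool = False

    def __post_init__(self) -> None:
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise ValueError(f"unknown functional class {self.functional_class!r}")
        if not self.gene and self.functional_class not in ("intergenic", "other"):
            raise ValueError(
                "a variant without a gene must be intergenic or 'other', got "
                f"{self.functional_class!r}"
            )


@dataclass
class ConsolidatedVariant:
    """Cross-caller/cross-platform merged record with evidence tier and flags."""

    key: VariantKey
    calls: tuple[VariantCall, ...] = ()
    tier: str = "single_technology"  # cross_platform | single_technology
    somatic: Optional[bool] = None  # None = unclassifiable
    novel: bool = False
    annotation: Annotation = field(default_factory=Annotation)

    @property
    def chrom(self) -> str:
        return self.key[0]

    @property
    def pos(self) -> int:
        return self.key[1]

    @property
    def ref(self) -> str:
        return self.key[2]

    @property
    def alt(self) -> str:
        return self.key[3]

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def platform_maf(self, platform: str) -> Optional[float]:
        """Best (maximum) MAF observed on a platform over all calls, or None."""
        mafs = [
            c.maf for c in self.calls if c.platform == platform and c.maf is not None
        ]
        return max(mafs) if mafs else None

    def platform_depth(self, platform: str) -> Optional[int]:
        depths = [c.depth for c in self.calls if c.platform == platform]
        return max(depths) if depths else None


def _record_depth_fields(rec, alt_index: int, n_alts: int) -> tuple[int, int]:
    """Recover (depth, alt_reads) from FORMAT AD/DP of the first sample or INFO."""
    depth = None
    alt_reads = None
    if rec.samples:
        sample = rec.samples[0]
        ad = sample.get("AD")
        if ad is not None and ad[0] is not None:
            # AD is Number=R: ref count followed by one count per ALT
            alt_reads = int(ad[1 + alt_index])
            depth = int(sum(x for x in ad if x is not None))
        dp = sample.get("DP")
        if dp is not None:
            depth = int(dp)
    if depth is None and "DP" in rec.info:
        depth = int(rec.info["DP"])
    if alt_reads is None and "AD" in rec.info:
        ad = rec.info["AD"]
        if isinstance(ad, (tuple, list)):
            ad = ad[alt_index] if len(ad) == n_alts else ad[1 + alt_index]
        alt_reads = int(ad)
    if depth is None or alt_reads is None:
        raise MissingDepthError(
            "cannot recover depth/alt-read counts from FORMAT AD/DP or INFO"
        )
    return depth, min(alt_reads, depth)


def read_callset(
    path: str, *, sample_role: str, platform: str, caller: str
) -> list[VariantCall]:
    """Read one caller's VCF into VariantCall records.

    Multi-allelic records are split into one record per ALT allele. Raises
    :class:`MissingDepthError` if depth fields are absent and
    :class:`VcfParseError` on malformed input.
    """
    calls: list[VariantCall] = []
    try:
        vcf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"{path}: {exc}") from exc
    with vcf:
        for i, rec in enumerate(vcf):
            try:
                alts = rec.alts or ()
                for alt_index, alt in enumerate(alts):
                    depth, alt_reads = _record_depth_fields(rec, alt_index, len(alts))
                    calls.append(
                        VariantCall(
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            sample_role=sample_role,
                            platform=platform,
                            caller=caller,
                            depth=depth,
                            alt_reads=alt_reads,
                        )
                    )
            except MissingDepthError:
                raise MissingDepthError(f"{path}: record {i + 1} at {rec.chrom}:{rec.pos}")
            except (ValueError, TypeError) as exc:
                raise VcfParseError(
                    f"{path}: record {i + 1} at {rec.chrom}:{rec.pos}: {exc}"
                ) from exc
    return calls


def read_callsets(
    paths: Sequence[str], metadata: Sequence[Mapping[str, str]]
) -> list[VariantCall]:
    """Read several per-caller VCFs; ``metadata[i]`` supplies
    sample_role/platform/caller for ``paths[i]``."""
    if len(paths) != len(metadata):
        raise ValueError("paths and metadata must align")
    calls: list[VariantCall] = []
    for path, meta in zip(paths, metadata):
        calls.extend(
            read_callset(
                path,
                sample_role=meta["sample_role"],
                platform=meta["platform"],
                caller=meta["caller"],
            )
        )
    return calls


_INFO_FIELDS = [
    ("TIER", "1", "String", "Evidence tier: cross_platform or single_technology"),
    ("SOMATIC", "0", "Flag", "Variant classified somatic"),
    ("UNCLASSIFIABLE", "0", "Flag", "Somatic status could not be decided"),
    ("NOVEL", "0", "Flag", "Not annotated in the germline variant database"),
    ("GENE", "1", "String", "Gene symbol"),
    ("FCLASS", "1", "String", "Functional class"),
    ("DMG", "0", "Flag", "Predicted damaging"),
    ("CONSPOS", "0", "Flag", "Conserved position"),
    ("CENSUS", "0", "Flag", "Cancer gene census membership"),
]


def _consolidated_header(variants: Sequence[ConsolidatedVariant]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    contigs = sorted({v.chrom for v in variants})
    maxpos: dict[str, int] = {}
    for v in variants:
        maxpos[v.chrom] = max(maxpos.get(v.chrom, 0), v.pos + len(v.ref))
    for contig in contigs:
        header.contigs.add(contig, length=maxpos[contig] + 1)
    for ident, number, typ, desc in _INFO_FIELDS:
        header.info.add(ident, number, typ, desc)
    return header


def write_consolidated(variants: Iterable[ConsolidatedVariant], path: str) -> None:
    """Serialize consolidated variants to a VCF with TIER/SOMATIC/... INFO keys.

    Round-trips through :func:`read_consolidated` without loss of the fields
    defined here (calls themselves are not serialized).
    """
    variants = sorted(variants, key=lambda v: v.key)
    header = _consolidated_header(variants)
    with pysam.VariantFile(path, "w", header=header) as out:
        for v in variants:
            rec = out.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt),
            )
            rec.info["TIER"] = v.tier
            if v.somatic:
                rec.info["SOMATIC"] = True
            if v.somatic is None:
                rec.info["UNCLASSIFIABLE"] = True
            if v.novel:
                rec.info["NOVEL"] = True
            ann = v.annotation
            if ann.gene:
                rec.info["GENE"] = ann.gene
            rec.info["FCLASS"] = ann.functional_class
            if ann.damaging:
                rec.info["DMG"] = True
            if ann.conserved_position:
                rec.info["CONSPOS"] = True
            if ann.cancer_census:
                rec.info["CENSUS"] = True
            out.write(rec)


def read_consolidated(path: str) -> list[ConsolidatedVariant]:
    """Inverse of :func:`write_consolidated` on the fields it defines."""
    out: list[ConsolidatedVariant] = []
    try:
        vcf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"{path}: {exc}") from exc
    with vcf:
        for rec in vcf:
            gene = rec.info.get("GENE", "")
            fclass = rec.info.get("FCLASS", "other")
            somatic: Optional[bool]
            if rec.info.get("UNCLASSIFIABLE", False):
                somatic = None
            else:
                somatic = bool(rec.info.get("SOMATIC", False))
            out.append(
                ConsolidatedVariant(
                    key=(rec.chrom, rec.pos, rec.ref, rec.alts[0]),
                    tier=rec.info.get("TIER", "single_technology"),
                    somatic=somatic,
                    novel=bool(rec.info.get("NOVEL", False)),
                    annotation=Annotation(
                        gene=gene,
                        functional_class=fclass,
                        damaging=bool(rec.info.get("DMG", False)),
                        conserved_position=bool(rec.info.get("CONSPOS", False)),
                        cancer_census=bool(rec.info.get("CENSUS", False)),
                    ),
                )
            )
    return out


def read_manifest(path: str) -> tuple[list[str], list[dict[str, str]]]:
    """Read a callset manifest TSV (path, sample_role, platform, caller)."""
    paths: list[str] = []
    meta: list[dict[str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "path":  # header row
                continue
            if len(fields) != 4:
                raise VcfParseError(f"manifest row needs 4 columns: {line!r}")
            paths.append(fields[0])
            meta.append(
                {"sample_role": fields[1], "platform": fields[2], "caller": fields[3]}
            )
    return paths, meta
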