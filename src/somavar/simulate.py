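"""Synthetic-data generation for every pipeline input, with ground truth.

The generator emulates a two-platform (WES + WGS) matched tumor/normal
sequencing design: per-caller call sets with configurable detection
probabilities and platform-private false positives, somatic SNVs drawn from a
mutational-signature mixture over the reference trinucleotide composition,
clonal heterozygous somatic MAFs centered on purity/2, a population panel
with per-gene rate multipliers (low multiplier = conserved gene), and planted
germline/somatic structural variants including insertion contigs with
control-read coverage profiles.

Everything is deterministic under a fixed seed; each ``simulate_*`` stage
draws from its own seed stream so stages are independently reproducible.
Truth tables carry enough labels to score every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .conservation import GeneModel
from .errors import SimulationError
from .signatures import SignatureCatalog, synthetic_catalog
from .spectrum import BASES, COMPLEMENT, pyrimidine_context
from .svs import ContigInsert, SVRecord
from .model import VariantCall

DEFAULT_CALLERS = {"WES": ("dibayes", "samtools", "gatk"), "WGS": ("samtools", "gatk")}

# stage ids for independent, reproducible seed streams
_STREAM_REFERENCE = 1
_STREAM_CALLSETS = 2
_STREAM_PANEL = 3
_STREAM_SVS = 4


@dataclass
class SimConfig:
    """Stated world of the simulation.

    Defaults follow the study design being emulated: tumor purity 0.30 (the
    MSI sample's estimated cellularity), ~200 cross-platform somatic SNVs,
    a 1092-sample population panel, WES/WGS mean depths inside the reported
    coverage ranges, and full caller sensitivity with no false positives
    unless injected.
    """

    seed: int = 0
    genome_length: int = 300_000
    n_genes: int = 50
    exons_per_gene: int = 4
    exon_length: int = 150
    purity: float = 0.30
    concentration: float = 100.0  # Beta concentration of somatic MAFs
    n_somatic_snvs: int = 200
    n_germline_snvs: int = 1000
    signature_mixture: Optional[dict[str, float]] = None
    planted_clusters: Sequence[tuple[int, int, int]] = ()  # (position, n_snvs, span_bp)
    platform_sensitivity: Optional[Mapping[tuple[str, str], float]] = None
    false_positives: Mapping[tuple[str, str], int] = field(default_factory=dict)
    depth: Mapping[str, int] = field(default_factory=lambda: {"WES": 60, "WGS": 40})
    binomial_reads: bool = False  # deterministic round(maf*depth) by default
    panel_samples: int = 1092
    panel_rate_per_bp: float = 9e-4  # coding non-syn variants per bp per sample
    gene_multipliers: Optional[Mapping[str, float]] = None
    sv_counts: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "deletion": (4, 3),
            "inversion": (4, 3),
            "tandem_duplication": (2, 2),
            "translocation": (2, 2),
        }
    )  # sv_type -> (n_germline, n_somatic)
    n_germline_insertions: int = 3
    n_somatic_insertions: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.purity <= 1:
            raise SimulationError("purity must be in (0, 1]")
        if self.signature_mixture is not None:
            total = sum(self.signature_mixture.values())
            if total <= 0:
                raise SimulationError("signature mixture weights must be positive")
            self.signature_mixture = {
                k: v / total for k, v in self.signature_mixture.items()
            }
        for name, value in (
            ("n_somatic_snvs", self.n_somatic_snvs),
            ("n_germline_snvs", self.n_germline_snvs),
            ("panel_samples", self.panel_samples),
        ):
            if value < 0:
                raise SimulationError(f"{name} must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))


@dataclass
class SimReference:
    """Synthetic reference: one contig plus a non-overlapping gene model."""

    chrom: str
    sequence: str
    genes: list[GeneModel]

    def to_fasta(self, path: Union[str, Path]) -> None:
        rec = SeqRecord(Seq(self.sequence), id=self.chrom, description="")
        SeqIO.write([rec], str(path), "fasta")

    def to_bed(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            for g in self.genes:
                for s, e in g.exons:  # 1-based inclusive -> BED half-open
                    fh.write(f"{g.chrom}\t{s - 1}\t{e}\t{g.gene}\n")


def simulate_reference(config: SimConfig) -> SimReference:
    """Random reference sequence with disjoint genes of known exon structure."""
    rng = config.rng(_STREAM_REFERENCE)
    seq = "".join(rng.choice(list(BASES), size=config.genome_length))
    genes: list[GeneModel] = []
    if config.n_genes > 0:
        intron = max(20, config.exon_length // 2)
        gene_span = config.exons_per_gene * config.exon_length + (
            config.exons_per_gene - 1
        ) * intron
        gap = 50
        needed = config.n_genes * (gene_span + gap)
        if needed > config.genome_length:
            raise SimulationError(
                f"cannot pack {config.n_genes} genes ({needed} bp) into "
                f"{config.genome_length} bp"
            )
        slack = (config.genome_length - needed) // max(config.n_genes, 1)
        cursor = 1
        for i in range(config.n_genes):
            start = cursor + int(rng.integers(0, slack + 1))
            exons = []
            pos = start
            for _ in range(config.exons_per_gene):
                exons.append((pos, pos + config.exon_length - 1))
                pos += config.exon_length + intron
            genes.append(GeneModel(gene=f"GENE{i + 1:03d}", chrom="chr1", exons=exons))
            cursor = start + gene_span + gap
    return SimReference(chrom="chr1", sequence=seq, genes=genes)


def _context_pools(
    sequence: str, rng: np.random.Generator
) -> dict[str, list[int]]:
    """Positions (1-based, shuffled) of each pyrimidine-centered trinucleotide."""
    pools: dict[str, list[int]] = {}
    for i in range(1, len(sequence) - 1):
        tri = sequence[i - 1 : i + 2]
        if "N" in tri:
            continue
        pools.setdefault(pyrimidine_context(tri), []).append(i + 1)
    for positions in pools.values():
        rng.shuffle(positions)
    return pools


def _gene_annotation(
    pos: int, genes: Sequence[GeneModel], rng: np.random.Generator
) -> tuple[str, str, bool, bool]:
    """(gene, functional_class, damaging, conserved_position) for a locus."""
    for g in genes:
        lo, hi = g.span
        if lo <= pos <= hi:
            if any(s <= pos <= e for s, e in g.exons):
                fclass = rng.choice(
                    ["synonymous", "nonsynonymous", "stopgain"], p=[0.25, 0.70, 0.05]
                )
                damaging = fclass == "nonsynonymous" and rng.random() < 0.5
                conserved_pos = fclass != "synonymous" and rng.random() < 0.3
                return g.gene, str(fclass), bool(damaging), bool(conserved_pos)
            return g.gene, "intronic", False, False
    return "", "intergenic", False, False


@dataclass
class CallsetSim:
    """Simulated per-platform per-caller call sets plus the truth table."""

    calls: dict[tuple[str, str, str], list[VariantCall]]  # (role, platform, caller)
    truth: pd.DataFrame
    pileup: pd.DataFrame
    chrom: str
    genome_length: int

    def all_calls(self) -> list[VariantCall]:
        return [c for group in self.calls.values() for c in group]

    def write_pileup(self, path: Union[str, Path]) -> None:
        self.pileup.to_csv(path, sep="\t", index=False)

    def write_truth(self, path: Union[str, Path]) -> None:
        self.truth.to_csv(path, sep="\t", index=False)

    def write_vcfs(self, outdir: Union[str, Path]) -> pd.DataFrame:
        """Write one VCF per (role, platform, caller); returns a manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = []
        for (role, platform, caller), calls in sorted(self.calls.items()):
            path = outdir / f"calls_{role}_{platform}_{caller}.vcf"
            _write_callset_vcf(calls, path, self.chrom, self.genome_length, role)
            rows.append((str(path), role, platform, caller))
        manifest = pd.DataFrame(
            rows, columns=["path", "sample_role", "platform", "caller"]
        )
        manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
        return manifest


def _write_callset_vcf(
    calls: Sequence[VariantCall],
    path: Union[str, Path],
    chrom: str,
    length: int,
    sample: str,
) -> None:
    header = pysam.VariantHeader()
    header.contigs.add(chrom, length=length)
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", "1", "Integer", "Read depth")
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in sorted(calls, key=lambda c: (c.chrom, c.pos, c.ref, c.alt)):
            rec = out.new_record(
                contig=call.chrom,
                start=call.pos - 1,
                stop=call.pos - 1 + len(call.ref),
                alleles=(call.ref, call.alt),
            )
            rec.samples[sample]["AD"] = (call.depth - call.alt_reads, call.alt_reads)
            rec.samples[sample]["DP"] = call.depth
            out.write(rec)


def _emit_reads(
    maf: float, depth: int, rng: np.random.Generator, binomial: bool
) -> tuple[int, int]:
    if maf <= 0:
        return depth, 0
    if binomial:
        return depth, int(rng.binomial(depth, maf))
    return depth, max(1, int(round(maf * depth)))


def simulate_callsets(
    config: SimConfig,
    reference: SimReference,
    catalog: Optional[SignatureCatalog] = None,
) -> CallsetSim:
    """Simulate truth variants and their per-platform per-caller call sets.

    Somatic SNVs are placed by drawing a signature from the mixture, a
    96-channel from that signature's profile, and a reference position whose
    trinucleotide matches the channel (either strand). Somatic MAFs are
    Beta-distributed with mean purity/2; germline MAFs are 0.5 (het) or 1.0
    (hom) in both tumor and normal. Each true variant enters each
    platform/caller call set with its detection probability; injected false
    positives are platform/caller-private and absent from the pileup table.
    """
    rng = config.rng(_STREAM_CALLSETS)
    seq = reference.sequence
    genes = reference.genes
    chrom = reference.chrom

    if catalog is None:
        names = (
            list(config.signature_mixture) if config.signature_mixture else None
        )
        catalog = synthetic_catalog(
            n_signatures=len(names) if names else 3, seed=config.seed
        )
        if names:
            catalog.profiles.columns = names
    mixture = config.signature_mixture or {
        name: 1.0 / len(catalog.names) for name in catalog.names
    }
    sig_names = list(mixture)
    sig_weights = np.array([mixture[n] for n in sig_names])

    pools = _context_pools(seq, rng)
    used: set[int] = set()

    def take_position(ctx: str) -> Optional[int]:
        pool = pools.get(ctx, [])
        while pool:
            pos = pool.pop()
            if pos not in used:
                used.add(pos)
                return pos
        return None

    alpha = config.purity / 2 * config.concentration
    beta = (1 - config.purity / 2) * config.concentration

    truth_rows = []

    def add_truth(pos, ref, alt, label, maf_t, maf_n, cluster_id="", signature=""):
        gene, fclass, damaging, conspos = _gene_annotation(pos, genes, rng)
        novel = label == "somatic" or (label == "germline" and rng.random() < 0.1)
        truth_rows.append(
            dict(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                label=label,
                cluster_id=cluster_id,
                signature=signature,
                true_maf_tumor=maf_t,
                true_maf_normal=maf_n,
                gene=gene,
                functional_class=fclass,
                damaging=damaging,
                conserved_position=conspos,
                novel=novel,
            )
        )

    # --- somatic SNVs from the signature mixture -----------------------------
    channel_names = list(catalog.profiles.index)
    for _ in range(config.n_somatic_snvs):
        pos = None
        for _attempt in range(100):
            sig = sig_names[rng.choice(len(sig_names), p=sig_weights)]
            profile = catalog.profiles[sig].to_numpy()
            channel = channel_names[rng.choice(96, p=profile)]
            five, ref_pyr, alt_pyr, three = channel[0], channel[2], channel[4], channel[6]
            ctx = five + ref_pyr + three
            pos = take_position(ctx)
            if pos is not None:
                break
        if pos is None:
            raise SimulationError("exhausted reference positions for signature contexts")
        genome_ref = seq[pos - 1]
        if genome_ref == ref_pyr:  # pyrimidine on the forward strand
            alt = alt_pyr
        else:
            alt = COMPLEMENT[alt_pyr]
        maf = float(rng.beta(alpha, beta))
        add_truth(pos, genome_ref, alt, "somatic", maf, 0.0, signature=sig)

    # --- planted SNV clusters (kataegis-like) --------------------------------
    for ci, (start, n_snvs, span_bp) in enumerate(config.planted_clusters):
        span_positions = [
            p
            for p in range(max(2, start), min(len(seq) - 1, start + span_bp))
            if p not in used
        ]
        if len(span_positions) < n_snvs:
            raise SimulationError(f"cluster {ci}: span too small for {n_snvs} SNVs")
        chosen = rng.choice(len(span_positions), size=n_snvs, replace=False)
        for idx in sorted(chosen):
            pos = span_positions[idx]
            used.add(pos)
            ref = seq[pos - 1]
            alt = str(rng.choice([b for b in BASES if b != ref]))
            maf = float(rng.beta(alpha, beta))
            add_truth(pos, ref, alt, "somatic", maf, 0.0, cluster_id=f"cluster{ci}")

    # --- germline SNVs --------------------------------------------------------
    free = np.setdiff1d(
        np.arange(2, len(seq) - 1), np.fromiter(used, dtype=int, count=len(used))
    )
    if len(free) < config.n_germline_snvs:
        raise SimulationError("genome too small for requested germline SNVs")
    for pos in rng.choice(free, size=config.n_germline_snvs, replace=False):
        pos = int(pos)
        used.add(pos)
        ref = seq[pos - 1]
        alt = str(rng.choice([b for b in BASES if b != ref]))
        maf = 0.5 if rng.random() < 2 / 3 else 1.0
        add_truth(pos, ref, alt, "germline", maf, maf)

    truth = pd.DataFrame(truth_rows).sort_values(["chrom", "pos"]).reset_index(drop=True)

    # --- read support (pileup) and call sets ---------------------------------
    sensitivity = config.platform_sensitivity or {}
    calls: dict[tuple[str, str, str], list[VariantCall]] = {
        (role, platform, caller): []
        for role in ("tumor", "normal")
        for platform, callers in DEFAULT_CALLERS.items()
        for caller in callers
    }
    pileup_rows = []
    for row in truth.itertuples(index=False):
        for role in ("tumor", "normal"):
            maf = row.true_maf_tumor if role == "tumor" else row.true_maf_normal
            for platform, callers in DEFAULT_CALLERS.items():
                depth, alt_reads = _emit_reads(
                    maf, config.depth[platform], rng, config.binomial_reads
                )
                pileup_rows.append(
                    (row.chrom, row.pos, row.ref, row.alt, role, platform, depth, alt_reads)
                )
                if alt_reads == 0:
                    continue
                for caller in callers:
                    p = sensitivity.get((platform, caller), 1.0)
                    if p >= 1.0 or rng.random() < p:
                        calls[(role, platform, caller)].append(
                            VariantCall(
                                chrom=row.chrom,
                                pos=int(row.pos),
                                ref=row.ref,
                                alt=row.alt,
                                sample_role=role,
                                platform=platform,
                                caller=caller,
                                depth=depth,
                                alt_reads=alt_reads,
                            )
                        )
    pileup = pd.DataFrame(
        pileup_rows,
        columns=["chrom", "pos", "ref", "alt", "sample_role", "platform", "depth", "alt_reads"],
    )

    # --- platform/caller-private false positives ------------------------------
    fp_rows = []
    for (platform, caller), n_fp in config.false_positives.items():
        free = [p for p in range(2, len(seq) - 1) if p not in used]
        for pos in rng.choice(len(free), size=n_fp, replace=False):
            pos = free[int(pos)]
            used.add(pos)
            ref = seq[pos - 1]
            alt = str(rng.choice([b for b in BASES if b != ref]))
            maf = float(rng.beta(alpha, beta))
            depth, alt_reads = _emit_reads(
                maf, config.depth[platform], rng, config.binomial_reads
            )
            calls[("tumor", platform, caller)].append(
                VariantCall(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    sample_role="tumor",
                    platform=platform,
                    caller=caller,
                    depth=depth,
                    alt_reads=alt_reads,
                )
            )
            fp_rows.append(
                dict(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    label="false_positive",
                    cluster_id="",
                    signature="",
                    true_maf_tumor=np.nan,
                    true_maf_normal=np.nan,
                    gene="",
                    functional_class="other",
                    damaging=False,
                    conserved_position=False,
                    novel=True,
                )
            )
    if fp_rows:
        truth = (
            pd.concat([truth, pd.DataFrame(fp_rows)], ignore_index=True)
            .sort_values(["chrom", "pos"])
            .reset_index(drop=True)
        )

    calls = {k: v for k, v in calls.items() if v}
    return CallsetSim(
        calls=calls,
        truth=truth,
        pileup=pileup,
        chrom=chrom,
        genome_length=len(seq),
    )


@dataclass
class PanelSim:
    """Simulated population panel with known per-gene rate multipliers."""

    counts: pd.DataFrame  # long: sample, gene, count
    multipliers: dict[str, float]  # truth: low multiplier = conserved gene

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.counts.to_csv(path, sep="\t", index=False)

    def write_truth(self, path: Union[str, Path]) -> None:
        pd.DataFrame(
            sorted(self.multipliers.items()), columns=["gene", "multiplier"]
        ).to_csv(path, sep="\t", index=False)


def simulate_panel(config: SimConfig, genes: Sequence[GeneModel]) -> PanelSim:
    """Per-sample exonic variant counts, Poisson with rate ∝ length × multiplier."""
    rng = config.rng(_STREAM_PANEL)
    if config.gene_multipliers is not None:
        multipliers = {g.gene: float(config.gene_multipliers[g.gene]) for g in genes}
    else:
        multipliers = {
            g.gene: float(rng.uniform(0.005, 2.0)) for g in genes
        }
    lengths = np.array([g.exonic_length for g in genes], dtype=float)
    mults = np.array([multipliers[g.gene] for g in genes])
    lam = config.panel_rate_per_bp * lengths * mults
    matrix = rng.poisson(lam, size=(config.panel_samples, len(genes)))
    samples = [f"HG{i + 1:05d}" for i in range(config.panel_samples)]
    counts = pd.DataFrame(matrix, index=samples, columns=[g.gene for g in genes])
    long = counts.reset_index(names="sample").melt(
        id_vars="sample", var_name="gene", value_name="count"
    )
    return PanelSim(counts=long, multipliers=multipliers)


@dataclass
class SVSim:
    """Planted structural variants with germline/somatic truth labels."""

    tumor_svs: list[SVRecord]
    control_svs: list[SVRecord]
    contigs: list[ContigInsert]
    truth: pd.DataFrame

    def write(self, outdir: Union[str, Path]) -> None:
        from .svs import write_coverage_tsv, write_sv_tsv

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_sv_tsv(self.tumor_svs, outdir / "svs_tumor.tsv")
        write_sv_tsv(self.control_svs, outdir / "svs_control.tsv")
        records = [
            SeqRecord(Seq(c.sequence), id=c.contig_id, description="")
            for c in self.contigs
        ]
        SeqIO.write(records, str(outdir / "contigs.fasta"), "fasta")
        write_coverage_tsv(
            {c.contig_id: c.control_coverage for c in self.contigs},
            outdir / "contig_coverage.tsv",
        )
        self.truth.to_csv(outdir / "sv_truth.tsv", sep="\t", index=False)


_SV_SIZES = {
    "deletion": (50, 500),
    "inversion": (200, 2000),
    "tandem_duplication": (100, 1000),
}


def simulate_svs(config: SimConfig, reference: Optional[SimReference] = None) -> SVSim:
    """Plant germline and somatic SVs plus insertion contigs with coverage.

    Germline interval SVs/translocations appear in both tumor and control call
    sets; somatic ones in the tumor only. Germline insertion contigs receive
    control coverage at >= 90% of positions, somatic ones below 90%.
    """
    rng = config.rng(_STREAM_SVS)
    length = reference.genome_length if hasattr(reference, "genome_length") else (
        len(reference.sequence) if reference is not None else config.genome_length
    )
    chrom = reference.chrom if reference is not None else "chr1"
    chrom2 = "chr2"

    tumor: list[SVRecord] = []
    control: list[SVRecord] = []
    truth_rows = []

    def support() -> tuple[int, int]:
        return int(rng.integers(3, 20)), int(rng.integers(3, 20))

    for sv_type, (n_germline, n_somatic) in config.sv_counts.items():
        for i in range(n_germline + n_somatic):
            label = "germline" if i < n_germline else "somatic"
            if sv_type == "translocation":
                p1 = int(rng.integers(1, length))
                p2 = int(rng.integers(1, length))
                rec = SVRecord(
                    sv_type=sv_type,
                    chrom1=chrom,
                    start1=p1,
                    end1=p1,
                    chrom2=chrom2,
                    start2=p2,
                    end2=p2,
                    supporting_pairs=support()[0],
                    supporting_splits=support()[1],
                    sample_role="tumor",
                )
            else:
                lo, hi = _SV_SIZES[sv_type]
                size = int(rng.integers(lo, hi))
                start = int(rng.integers(1, max(2, length - size)))
                rec = SVRecord(
                    sv_type=sv_type,
                    chrom1=chrom,
                    start1=start,
                    end1=start + size - 1,
                    supporting_pairs=support()[0],
                    supporting_splits=support()[1],
                    sample_role="tumor",
                )
            tumor.append(rec)
            if label == "germline":
                control.append(
                    SVRecord(
                        sv_type=rec.sv_type,
                        chrom1=rec.chrom1,
                        start1=rec.start1,
                        end1=rec.end1,
                        chrom2=rec.chrom2,
                        start2=rec.start2,
                        end2=rec.end2,
                        supporting_pairs=support()[0],
                        supporting_splits=support()[1],
                        sample_role="normal",
                    )
                )
            truth_rows.append(
                dict(
                    kind="sv",
                    sv_type=sv_type,
                    id=f"{sv_type}:{rec.chrom1}:{rec.start1}",
                    label=label,
                )
            )

    contigs: list[ContigInsert] = []
    n_ins = config.n_germline_insertions + config.n_somatic_insertions
    for i in range(n_ins):
        label = "germline" if i < config.n_germline_insertions else "somatic"
        clen = int(rng.integers(80, 200))
        seq = "".join(rng.choice(list(BASES), size=clen))
        if label == "germline":
            frac = float(rng.uniform(0.90, 1.0))
        else:
            frac = float(rng.uniform(0.30, 0.85))
        n_cov = int(np.ceil(frac * clen)) if label == "germline" else int(frac * clen)
        cov = np.zeros(clen, dtype=int)
        covered_idx = rng.choice(clen, size=n_cov, replace=False)
        cov[covered_idx] = rng.poisson(8, size=n_cov) + 1
        contig_id = f"contig{i + 1}"
        contigs.append(
            ContigInsert(
                contig_id=contig_id,
                sequence=seq,
                putative_insert_positions=[(chrom, int(rng.integers(1, length)))],
                control_coverage=cov,
            )
        )
        truth_rows.append(dict(kind="insertion", sv_type="insertion", id=contig_id, label=label))

    truth = pd.DataFrame(truth_rows)
    return SVSim(tumor_svs=tumor, control_svs=control, contigs=contigs, truth=truth)
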