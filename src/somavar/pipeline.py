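"""End-to-end orchestration of the interpretation pipeline.

Stages run in dependency order: consolidate -> somatic -> purity / spectrum /
signatures / candidates; ECS and pathway burden from the population panel;
SV filtering independently. Inputs either come from the synthetic generator
(default) or from user-supplied files; all referenced files are validated
before any stage runs. A machine-readable JSON manifest records the seed,
parameters and per-stage counts, and is byte-identical across reruns with the
same configuration.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import burden as burden_mod
from . import consolidate as cons
from . import conservation as consv
from . import model
from . import purity as purity_mod
from . import signatures as sig_mod
from . import simulate as sim
from . import spectrum as spec_mod
from . import svs as svs_mod
from .errors import InsufficientDataError, SomavarError

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "consolidate",
    "purity",
    "spectrum",
    "signatures",
    "ecs",
    "candidates",
    "burden",
    "sv",
)

_STAGE_DEPS = {
    "purity": ("consolidate",),
    "spectrum": ("consolidate",),
    "signatures": ("consolidate",),
    "candidates": ("consolidate", "ecs"),
    "burden": ("consolidate",),
}


@dataclass
class RunConfig:
    """Parameters for one pipeline run (YAML-loadable; CLI flags override)."""

    seed: int = 0
    outdir: str = "somavar_run"
    stages: Sequence[str] = ALL_STAGES
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    inputs: Optional[dict] = None  # externally supplied input paths
    maf_threshold: float = cons.MAF_THRESHOLD
    normal_maf_max: float = cons.NORMAL_MAF_MAX
    min_reads: int = cons.MIN_READS
    purity_method: str = "mode"
    cluster_rules: Sequence[tuple[int, int]] = spec_mod.DEFAULT_CLUSTER_RULES
    nmf_k: int = 2
    min_exposure: float = 0.06
    ecs_threshold: float = consv.CONSERVED_THRESHOLD
    sv_overlap: float = 0.5
    sv_slop: int = 100
    sv_min_support: int = 3
    n_go_terms: int = 20

    def resolved_stages(self) -> list[str]:
        selected = set(self.stages)
        changed = True
        while changed:
            changed = False
            for stage in list(selected):
                for dep in _STAGE_DEPS.get(stage, ()):
                    if dep not in selected:
                        selected.add(dep)
                        changed = True
        return [s for s in ALL_STAGES if s in selected]

    @classmethod
    def from_yaml(cls, path: Union[str, Path], **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


_INPUT_KEYS = (
    "manifest",
    "pileup",
    "reference",
    "gene_bed",
    "panel",
    "gene_terms",
    "catalog",
    "sv_tumor",
    "sv_control",
    "contig_coverage",
)


def _validate_inputs(inputs: Mapping[str, str]) -> None:
    missing = [
        f"{k}={v}" for k, v in inputs.items() if v is not None and not Path(v).exists()
    ]
    if missing:
        raise SomavarError("missing input files: " + ", ".join(missing))


def _synthetic_go_map(genes: Sequence[str], n_terms: int, seed: int) -> dict[str, list[str]]:
    rng = np.random.default_rng(np.random.SeedSequence((seed, 99)))
    terms = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    return {
        g: sorted(
            rng.choice(terms, size=int(rng.integers(1, 4)), replace=False).tolist()
        )
        for g in genes
    }


def _annotate_from_truth(
    variants: Sequence[model.ConsolidatedVariant], truth: pd.DataFrame
) -> list[model.ConsolidatedVariant]:
    """Attach the generator's annotation flags (standing in for an external
    annotator) to consolidated variants by key."""
    lookup = {}
    for row in truth.itertuples(index=False):
        lookup[(str(row.chrom), int(row.pos), row.ref, row.alt)] = row
    out = []
    for v in variants:
        row = lookup.get(v.key)
        if row is None:
            out.append(v)
            continue
        ann = model.Annotation(
            gene=row.gene,
            functional_class=row.functional_class,
            damaging=bool(row.damaging),
            conserved_position=bool(row.conserved_position),
        )
        out.append(replace(v, novel=bool(row.novel), annotation=ann))
    return out


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run the selected stages; returns the manifest (also written to JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.resolved_stages()
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "stages": stages,
        "parameters": {
            "maf_threshold": config.maf_threshold,
            "normal_maf_max": config.normal_maf_max,
            "min_reads": config.min_reads,
            "purity_method": config.purity_method,
            "cluster_rules": [list(r) for r in config.cluster_rules],
            "nmf_k": config.nmf_k,
            "min_exposure": config.min_exposure,
            "ecs_threshold": config.ecs_threshold,
            "sv_overlap": config.sv_overlap,
            "sv_slop": config.sv_slop,
        },
        "counts": {},
    }
    counts = manifest["counts"]

    if config.inputs is not None:
        _validate_inputs(config.inputs)

    sim_cfg = sim.SimConfig(seed=config.seed, **config.sim)
    catalog: Optional[sig_mod.SignatureCatalog] = None

    t0 = time.perf_counter()
    if config.inputs is None:
        # synthetic mode: generate all inputs under outdir/inputs
        indir = outdir / "inputs"
        indir.mkdir(exist_ok=True)
        reference = sim.simulate_reference(sim_cfg)
        reference.to_fasta(indir / "reference.fasta")
        reference.to_bed(indir / "genes.bed")
        catalog = sig_mod.synthetic_catalog(n_signatures=3, seed=sim_cfg.seed)
        catalog.to_tsv(indir / "catalog.tsv")
        callsets = sim.simulate_callsets(sim_cfg, reference, catalog)
        callsets.write_vcfs(indir)
        callsets.write_pileup(indir / "pileup.tsv")
        callsets.write_truth(indir / "truth.tsv")
        manifest_df = pd.read_csv(indir / "manifest.tsv", sep="\t")
        truth = callsets.truth
        genes = reference.genes
        ref_for_spectrum: Any = {reference.chrom: reference.sequence}
        panel_sim = sim.simulate_panel(sim_cfg, genes)
        panel_sim.to_tsv(indir / "panel_counts.tsv")
        panel_counts = panel_sim.counts
        svsim = sim.simulate_svs(sim_cfg, reference)
        svsim.write(indir)
        sv_tumor, sv_control, contigs = svsim.tumor_svs, svsim.control_svs, svsim.contigs
        pileup = callsets.pileup
    else:
        inp = config.inputs
        manifest_df = pd.read_csv(inp["manifest"], sep="\t")
        truth = None
        genes = consv.read_gene_bed(inp["gene_bed"]) if inp.get("gene_bed") else []
        ref_for_spectrum = inp.get("reference")
        panel_counts = (
            pd.read_csv(inp["panel"], sep="\t") if inp.get("panel") else None
        )
        if inp.get("catalog"):
            catalog = sig_mod.SignatureCatalog.from_tsv(inp["catalog"])
        sv_tumor = svs_mod.read_sv_tsv(inp["sv_tumor"]) if inp.get("sv_tumor") else []
        sv_control = (
            svs_mod.read_sv_tsv(inp["sv_control"]) if inp.get("sv_control") else []
        )
        contigs = []
        pileup = pd.read_csv(inp["pileup"], sep="\t") if inp.get("pileup") else None
    logger.info("inputs ready in %.2fs", time.perf_counter() - t0)

    calls = model.read_callsets(
        manifest_df["path"].tolist(),
        manifest_df[["sample_role", "platform", "caller"]].to_dict("records"),
    )
    support = cons.SupportTable(pileup) if pileup is not None else None

    somatic_cross: list[model.ConsolidatedVariant] = []
    conserved: set[str] = set()
    tumor_flagged: list[model.ConsolidatedVariant] = []

    if "consolidate" in stages:
        t0 = time.perf_counter()
        tiers = cons.classify_tier(calls, config.maf_threshold, support)
        tumor = tiers.get("tumor", [])
        normal = tiers.get("normal", [])
        tumor_flagged = cons.extract_somatic(
            tumor, normal, support, config.normal_maf_max, config.min_reads
        )
        if truth is not None:
            tumor_flagged = _annotate_from_truth(tumor_flagged, truth)
        somatic_cross = [
            v for v in tumor_flagged if v.somatic and v.tier == cons.CROSS_PLATFORM
        ]
        model.write_consolidated(tumor_flagged, str(outdir / "consolidated_tumor.vcf"))
        counts["cross_platform"] = sum(
            1 for v in tumor_flagged if v.tier == cons.CROSS_PLATFORM
        )
        counts["single_technology"] = sum(
            1 for v in tumor_flagged if v.tier == cons.SINGLE_TECHNOLOGY
        )
        counts["somatic"] = len(somatic_cross)
        logger.info("consolidate: %.2fs", time.perf_counter() - t0)

    if "ecs" in stages and panel_counts is not None and genes:
        t0 = time.perf_counter()
        stats = consv.build_panel_stats(panel_counts, genes)
        table = consv.ecs_table(stats, config.ecs_threshold)
        table.to_csv(outdir / "ecs.tsv", sep="\t", index=False)
        conserved = set(consv.conserved_genes(stats, config.ecs_threshold))
        counts["conserved_genes"] = len(conserved)
        logger.info("ecs: %.2fs", time.perf_counter() - t0)

    if "candidates" in stages:
        candidates = cons.select_candidates(somatic_cross, conserved)
        counts["candidates"] = len(candidates)
        model.write_consolidated(candidates, str(outdir / "candidates.vcf"))
        report = cons.build_report(calls, tumor_flagged, candidates)
        report.to_tsv(outdir / "filter_report.tsv")

    somatic_snvs = [
        v.key for v in somatic_cross if v.is_snv
    ]

    if "purity" in stages:
        t0 = time.perf_counter()
        wgs_mafs = [
            v.platform_maf("WGS") for v in somatic_cross if v.is_snv
        ]
        try:
            est = purity_mod.estimate_purity(
                [m for m in wgs_mafs if m is not None], method=config.purity_method
            )
            manifest["purity"] = {
                "estimate": round(est.estimate, 4),
                "n_variants": est.n_variants,
                "method": est.method,
            }
            pd.DataFrame([manifest["purity"]]).to_csv(
                outdir / "purity.tsv", sep="\t", index=False
            )
        except InsufficientDataError as exc:
            manifest["purity"] = {"error": str(exc)}
        logger.info("purity: %.2fs", time.perf_counter() - t0)

    spectrum = None
    if "spectrum" in stages and ref_for_spectrum is not None:
        t0 = time.perf_counter()
        spectrum = spec_mod.build_spectrum(somatic_snvs, ref_for_spectrum)
        spectrum.counts6.to_csv(outdir / "spectrum6.tsv", sep="\t", header=["count"])
        spectrum.counts96.to_csv(outdir / "spectrum96.tsv", sep="\t", header=["count"])
        spectrum.normalized96.to_csv(
            outdir / "spectrum96_normalized.tsv", sep="\t", header=["log10_norm"]
        )
        spec_mod.rainfall(somatic_snvs).to_csv(
            outdir / "rainfall.tsv", sep="\t", index=False
        )
        clusters = spec_mod.detect_clusters(somatic_snvs, config.cluster_rules)
        with open(outdir / "clusters.bed", "w") as fh:
            for w in clusters:
                fh.write(
                    f"{w.chrom}\t{w.start - 1}\t{w.end}\t"
                    f"rule_{w.rule[0]}bp_{w.rule[1]}snvs\t{w.n_snvs}\n"
                )
        counts["snv_clusters"] = len(clusters)
        counts["spectrum_snvs"] = spectrum.n_snvs
        logger.info("spectrum: %.2fs", time.perf_counter() - t0)

    if "signatures" in stages and spectrum is not None and spectrum.n_snvs > 0:
        t0 = time.perf_counter()
        if catalog is not None:
            fit = sig_mod.fit_exposures(
                spectrum.counts96, catalog, config.min_exposure
            )
            manifest["exposures"] = {
                k: round(float(v), 4) for k, v in fit.exposures.items()
            }
            manifest["exposures"]["unknown"] = round(fit.unknown_fraction, 4)
            fit.exposures.to_csv(outdir / "exposures.tsv", sep="\t", header=["exposure"])
        # de-novo extraction on two positional pseudo-samples
        median_pos = float(np.median([p for _, p, _, _ in somatic_snvs])) if somatic_snvs else 0
        left = [s for s in somatic_snvs if s[1] <= median_pos]
        right = [s for s in somatic_snvs if s[1] > median_pos]
        if left and right:
            mat = pd.DataFrame(
                {
                    "left": spec_mod.build_spectrum(left, ref_for_spectrum).counts96,
                    "right": spec_mod.build_spectrum(right, ref_for_spectrum).counts96,
                }
            )
            nmf = sig_mod.extract_signatures(
                mat, k=min(config.nmf_k, 2), seed=config.seed
            )
            nmf.profiles.to_csv(outdir / "denovo_signatures.tsv", sep="\t")
            manifest["nmf_error"] = round(nmf.reconstruction_error, 6)
        logger.info("signatures: %.2fs", time.perf_counter() - t0)

    if "burden" in stages and panel_counts is not None and genes:
        t0 = time.perf_counter()
        go_map = _synthetic_go_map(
            [g.gene for g in genes], config.n_go_terms, config.seed
        )
        tumor_gene_variants = [
            (v.annotation.gene, v.annotation.damaging)
            for v in tumor_flagged
            if v.somatic and v.annotation.gene
        ]
        tumor_loads = burden_mod.term_load(tumor_gene_variants, go_map)
        panel_loads = burden_mod.panel_loads_from_counts(panel_counts, go_map)
        stats = burden_mod.compare_to_panel_loads(tumor_loads, panel_loads)
        burden_mod.term_stats_table(stats).to_csv(
            outdir / "burden.tsv", sep="\t", index=False
        )
        counts["enriched_terms"] = sum(
            1 for s in stats if s.enriched_by_genes or s.enriched_by_variants
        )
        logger.info("burden: %.2fs", time.perf_counter() - t0)

    if "sv" in stages and (sv_tumor or contigs):
        t0 = time.perf_counter()
        tumor_q = svs_mod.quality_filter(sv_tumor, config.sv_min_support)
        control_q = svs_mod.quality_filter(sv_control, config.sv_min_support)
        somatic, nonoverlap = svs_mod.somatic_svs(
            tumor_q, control_q, config.sv_overlap, config.sv_slop
        )
        svs_mod.write_sv_tsv(somatic, outdir / "somatic_svs.tsv")
        counts["somatic_svs"] = len(somatic)
        counts["somatic_svs_nonoverlapping"] = nonoverlap
        if genes:
            svs_mod.annotate_sv_genes(somatic, genes).to_csv(
                outdir / "somatic_sv_genes.tsv", sep="\t", index=False
            )
        if contigs:
            ins = svs_mod.classify_insertions(contigs, genes=genes or None)
            ins.to_csv(outdir / "insertions.tsv", sep="\t", index=False)
            counts["somatic_insertions"] = int((ins["label"] == "somatic").sum())
            counts["germline_insertions"] = int((ins["label"] == "germline").sum())
        logger.info("sv: %.2fs", time.perf_counter() - t0)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
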