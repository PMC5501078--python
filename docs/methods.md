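# Methods

This note documents the models and procedures implemented in `somavar`, the
assumptions behind them, the defaults that matter, what the synthetic-data
generator does and does not emulate, and the numerical choices made where the
design was open.

## Scope and data model

The package operates downstream of read mapping and raw variant calling: its
inputs are per-caller VCFs for a matched tumor/normal pair sequenced on two
platforms (WES and WGS), a gene exon model (BED), a population panel
(multi-sample VCF or per-gene count table), a 96-channel signature catalog
(TSV), structural-variant calls (BEDPE-like TSV) and assembled insertion
contigs (FASTA) with control-read coverage (TSV). Annotations (gene,
functional class, damaging prediction, conservation flags, database
membership) arrive as input flags; no annotator is bundled.

Coordinates are 1-based inclusive everywhere (VCF convention); BED input is
converted at the reader boundary. Variants are keyed by
`(chrom, pos, ref, alt)` after reduction to minimal representation: shared
trailing bases are trimmed, then shared leading bases with the position
advanced. This merges the padded-representation differences between callers.
Full left-alignment against the reference (relevant only for indels inside
homopolymer/repeat runs) is intentionally not performed — the per-caller
readers do not require the reference sequence, and conflicting REF alleles at
one position are deliberately kept as distinct variants rather than
reconciled.

## Cross-platform consolidation

The tier rule: a variant called by ≥ 1 caller on either platform is
*cross-platform* iff its MAF is **strictly** greater than the threshold
(default 0.05) on both platforms in the same sample role; ties at the
threshold fail. Per platform the best (maximum) MAF over that platform's
calls is used; a platform without a call contributes MAF evidence through a
pileup-support table `(chrom, pos, ref, alt, sample_role, platform, depth,
alt_reads)`, reflecting validation against the raw data of the other
technology without a formal call. Depth 0 means "no support" and fails any
threshold. Calls from tumor and normal under one key are split by role
before classification, and every variant lands in exactly one tier.

Somatic status requires: absent from all matched-normal call sets; normal
MAF ≤ `normal_maf_max` (default 0.05 — the bound is a parameter because no
published value exists for it) at the position on every platform with normal
data; and tumor depth ≥ `min_reads` (default 3) on each platform where
coverage is known. A tumor variant with no matched-normal evidence at all is
*unclassifiable* (`somatic = None`), never somatic.

Candidate selection keeps novel somatic exonic variants that are stopgain,
or damaging and either at a conserved position or in a conserved gene (by
ECS). Indels flow through the same tiering; their extra criteria (frameshift,
novel) act through the functional-class annotation at candidate selection.

## Purity

Model: somatic variants are clonal, heterozygous, in diploid copy-neutral
regions, so E[MAF] = purity/2 and the estimate is 2× a central statistic of
the MAF distribution, clipped to (0, 1]. Default statistic: the mode of a
Gaussian KDE (absolute bandwidth 0.03, converted to scipy's scale factor;
evaluated on a 5×10⁻⁴ grid) over MAFs in (0.05, 0.5] — the mode is robust to
a subclonal low-MAF tail, which would bias mean or median downward. The
median is available (`method="median"`). A zero-variance sample
short-circuits to the constant (the KDE factor is undefined there). Fewer
than 20 usable MAFs raise an error instead of returning a silent estimate.
Copy-number-aware purity and clonality decomposition are out of scope.
Measured accuracy (test suite): mean absolute error ≤ 0.05 over purities
0.2–0.8 with 500 Beta-distributed MAFs per replicate.

## Spectrum, rainfall, cluster windows

Six substitution classes are pyrimidine-referenced (purine-reference SNVs
are reverse-complemented), with 96 channels ordered class-major, then 5′
base, then 3′ base (`A[C>A]A`, `A[C>A]C`, …). SNVs at contig edges or in
`N` contexts are excluded and counted. A REF allele that disagrees with the
reference raises an error listing the offending records.

The normalized heatmap matrix is
`log10((counts96/total) / ref_context_freq)`, with the 32 pyrimidine-centered
reference trinucleotide frequencies in the denominator. Channels with zero
counts receive a pseudo-count of 0.5 before the transform (display-only
quantity; the log base and zero-handling were open choices).

Cluster detection reports, for each rule `(window_bp, min_snvs)` — defaults
(160, 8) and (5000, 50) — every maximal merged span of qualifying windows,
where a window qualifies when ≥ `min_snvs` SNVs fall within `window_bp`
consecutive bases. Windows are anchored on SNV positions (two-pointer sweep);
merged spans may exceed `window_bp` by construction. The suite checks exact
agreement with a brute-force all-pairs oracle.

Sliding-window coverage summaries use window 150,000 / step 75,000 by
default, with the exported mean capped at 100.

## Signatures

*Extraction* is multiplicative-update NMF on the 96×samples count matrix,
minimizing Frobenius error, with the objective asserted non-increasing at
every iteration; 50 random restarts (seeds spawned from the user seed) and
the best fit kept together with its restart seed. Profiles are
column-normalized; contributions absorb the scale.

Identifiability caveat: when every sample is a well-blended mixture, the
Frobenius-optimal rank-k cone is spanned by mixtures of the true profiles
(and under Poisson noise a mixed factorization can measurably beat the
ground truth), so truth-level recovery requires near-pure samples anchoring
the cone — the recovery tests simulate such panels, and a green test
establishes recovery only in that regime.

*Refitting* normalizes the count vector and solves non-negative least
squares against the catalog profiles; exposures below `min_exposure`
(default 0.06, the deconstructSigs convention) are zeroed and the fit re-run
on the survivors until stable. `unknown_fraction = 1 − Σ exposures` (the
NNLS solution is scaled down in the rare overshoot case so the identity
holds with non-negative unknown mass). Reconstruction error is the cosine
distance between the normalized spectrum and its reconstruction. Recovery
accuracy depends on catalog conditioning: for disjoint-support profiles the
±0.05 bound at n = 1000 draws holds with margin; for strongly collinear
profiles NNLS variance grows and no such bound is guaranteed.

## Exonic conservation score

`ECS(g) = (V_g · L_tot) / (L_g · V_avg · S)` with V_g the gene's coding
non-synonymous panel variant count (carriers summed over samples), L_g its
exon-union length, L_tot the union length over all modeled genes, V_avg the
mean per-sample exonic variant count and S the panel size. This reading makes
ECS a dimensionless rate ratio: the gene's per-bp exonic mutation rate over
the panel-wide average, with the identity `Σ_g ECS_g·L_g / L_tot = 1`
whenever every panel variant lies in a modeled gene (asserted to 1e-9 in the
suite). Averaging V over genes instead of samples is exposed behind
`avg_over="genes"` but is not the default, because only the per-sample
reading yields the rate-ratio interpretation. Variants in overlapping genes
count for both genes (scores should not depend on arbitrary tie-breaks);
variants outside all exons are ignored with a logged count but do not enter
V_avg either. Genes with ECS < 0.01 (strict) are conserved; V_g = 0 gives
ECS = 0 (maximally conserved), while zero denominators raise errors.

## Pathway burden

Only damaging-flagged variants count. A variant contributes to every GO term
its gene maps to; gene counts are distinct genes per term. Enrichment is a
strict comparison against the **maximum** per-sample load in the panel —
never a pooled count, which is provably weaker — so a tumor indistinguishable
from the panel is never flagged. Under exchangeability the per-term
enrichment rate is at most 1/(S+1), with ties in discrete counts pushing it
lower. GO hierarchy propagation is off: the gene→term map is taken as given.

## Structural variants

Split-read filter: quality ≥ 35 at ≥ 95 positions, ≤ 2 alignment parts,
≥ 92 mapped bases (all boundaries inclusive as stated). Insertion contigs are
germline when control reads cover ≥ 90% of positions (90/100 is germline,
89/100 somatic); classification is monotone in control coverage. Somatic
classification of interval SVs uses reciprocal overlap ≥ 0.5 against
same-type control SVs; translocations match when both breakpoints fall
within 100 bp (slop). Both parameters are exposed — the original per-tool
matching rules are not public — as is the combined support minimum
(pairs + splits ≥ 3) of the quality filter. "Non-overlapping" counts merge
mutually overlapping somatic SVs of one type into clusters (union-find) and
count clusters. Deletions must exceed 5 bp. A k-mer (k = 31) exact matcher
can produce contig coverage from control reads for end-to-end synthetic
tests; it is explicitly not a re-aligner replacement.

## Synthetic-data generator

The generator emulates the two-platform matched tumor/normal design with a
single ~300 kb contig, 50 disjoint genes (4 × 150 bp exons), tumor purity
0.30, 200 somatic and 1000 germline SNVs, callers {dibayes, samtools, gatk}
on WES and {samtools, gatk} on WGS, mean depths 60× (WES) and 40× (WGS), a
1092-sample panel, and planted germline/somatic SVs and insertion contigs.
Somatic SNVs are placed by drawing a signature from the mixture, a channel
from its profile, and a reference position whose trinucleotide matches the
channel on either strand; somatic MAFs are Beta with mean purity/2 and
concentration 100; germline MAFs are exactly 0.5 (het, 2/3 of sites) or 1.0.
Read support is deterministic by default (`alt_reads = round(maf·depth)`),
with binomial sampling available — "noise" enters through per-caller
detection probabilities and injected platform/caller-private false positives
(default off), which have no pileup rows and therefore can never become
cross-platform or somatic. Panel counts are Poisson with rate
`9×10⁻⁴/bp × length × multiplier`; the rate is calibrated so a 600 bp toy
gene sees ~0.54 variants/sample, the per-gene statistic of a real
1000-Genomes-scale panel (matching the per-bp exome rate instead would make
the toy panel ~4× noisier per gene than the system being emulated).
Per-gene multipliers are drawn from U(0.005, 2), so low-multiplier genes are
known conserved truth. All stages draw from per-stage child seeds of the
master seed and are byte-deterministic.

Not emulated: read-level artifacts (no FASTQ/BAM), alignment error,
copy-number variation and subclonality, overlapping genes, indel calls in
the SNV generator, and realistic genome composition (the reference is i.i.d.
uniform ACGT). A green pipeline test therefore establishes the correctness
of the interpretation logic on its stated inputs, not robustness to
upstream calling artifacts.

## Scoring conventions

Somatic precision is computed over all reported cross-platform somatic
variants (unconditional). Recall is computed over truth somatic variants
*eligible* under the pipeline's own stated filters — emitted MAF strictly
above the threshold on both platforms and depth ≥ 3 — because a variant the
cross-platform rule is defined to drop (e.g. a true MAF below 5%) is the
filter working as specified, not a recovery failure.

## Known limitations

- Purity assumes diploidy and clonality; CNV-heavy or highly subclonal
  tumors will be misestimated by design.
- The tier rule treats per-platform MAF as exchangeable across callers
  (maximum over calls); per-caller quality scores are not modeled.
- ECS inherits the panel's annotation choices; with very short genes the
  Poisson noise floor makes the 0.01 conserved threshold conservative.
- NMF extraction reports the best of 50 restarts; global optimality is not
  guaranteed, and profile recovery requires near-pure samples (above).
- SV matching uses single-breakpoint slop and reciprocal overlap only; no
  orientation/strand of breakends is modeled.
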