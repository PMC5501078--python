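"""Mutation spectra, rainfall distances, SNV cluster (kataegis) detection,
and sliding-window coverage summaries.

Substitution classes are pyrimidine-referenced: every SNV whose reference
base is a purine is reverse-complemented, yielding the six standard classes
C>A, C>G, C>T, T>A, T>C, T>G. The 96-channel spectrum additionally records
the flanking 5' and 3' reference bases.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
import pyfaidx

from .errors import ReferenceMismatchError

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
BASES = ("A", "C", "G", "T")
CLASSES6 = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: canonical order of the 96 channels: class-major, then 5' base, then 3' base
CHANNELS96 = tuple(
    f"{five}[{cls}]{three}" for cls in CLASSES6 for five in BASES for three in BASES
)

#: the 32 pyrimidine-centered reference trinucleotides
TRINUCS32 = tuple(
    f"{five}{center}{three}" for center in ("C", "T") for five in BASES for three in BASES
)


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


def pyrimidine_context(trinuc: str) -> str:
    """Collapse a trinucleotide to its pyrimidine-centered strand."""
    trinuc = trinuc.upper()
    return trinuc if trinuc[1] in ("C", "T") else revcomp(trinuc)


def classify_snv(ref: str, alt: str, trinuc: str) -> tuple[str, str]:
    """Return (class, channel) for an SNV with its reference trinucleotide."""
    ref, alt, trinuc = ref.upper(), alt.upper(), trinuc.upper()
    if trinuc[1] != ref:
        raise ValueError(f"trinucleotide {trinuc} center != ref {ref}")
    if ref in ("G", "A"):
        ref, alt, trinuc = COMPLEMENT[ref], COMPLEMENT[alt], revcomp(trinuc)
    cls = f"{ref}>{alt}"
    return cls, f"{trinuc[0]}[{cls}]{trinuc[2]}"


Reference = Union[str, Path, Mapping[str, str]]

Snv = tuple[str, int, str, str]  # chrom, pos (1-based), ref, alt


def _as_sequences(reference: Reference) -> Mapping[str, str]:
    if isinstance(reference, Mapping):
        return {k: str(v).upper() for k, v in reference.items()}
    fasta = pyfaidx.Fasta(str(reference))
    return {name: str(fasta[name][:]).upper() for name in fasta.keys()}


def reference_context_freq(reference: Reference) -> pd.Series:
    """Frequencies of the 32 pyrimidine-centered trinucleotides in a reference."""
    seqs = _as_sequences(reference)
    counts = {t: 0 for t in TRINUCS32}
    for seq in seqs.values():
        for i in range(len(seq) - 2):
            tri = seq[i : i + 3]
            if "N" in tri:
                continue
            counts[pyrimidine_context(tri)] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("reference too short to contain any trinucleotide")
    return pd.Series({t: c / total for t, c in counts.items()}, name="freq")


@dataclass
class SpectrumMatrix:
    """Six-class and 96-channel somatic SNV spectra plus normalized form."""

    counts6: pd.Series  # index CLASSES6
    counts96: pd.Series  # index CHANNELS96
    ref_context_freq: pd.Series  # index TRINUCS32
    normalized96: pd.Series  # log10 of frequency-corrected channel fractions
    n_excluded: int = 0  # SNVs at contig edges without a full trinucleotide

    @property
    def n_snvs(self) -> int:
        return int(self.counts96.sum())


def _channel_trinuc(channel: str) -> str:
    # "A[C>T]G" -> "ACG"
    return channel[0] + channel[2] + channel[6]


def normalize96(counts96: pd.Series, ref_context_freq: pd.Series) -> pd.Series:
    """Reference-frequency-corrected, log10-transformed channel fractions.

    Zero channels receive a pseudo-count of 0.5 before the log transform so
    the result is finite everywhere (display-only quantity).
    """
    total = counts96.sum()
    if total == 0:
        raise ValueError("empty spectrum cannot be normalized")
    adj = counts96.astype(float).where(counts96 > 0, 0.5)
    ctx_freq = np.array([ref_context_freq[_channel_trinuc(ch)] for ch in counts96.index])
    with np.errstate(divide="ignore"):
        vals = np.log10((adj.to_numpy() / total) / ctx_freq)
    return pd.Series(vals, index=counts96.index, name="normalized96")


def build_spectrum(snvs: Iterable[Snv], reference: Reference) -> SpectrumMatrix:
    """Count somatic SNVs into 6-class / 96-channel spectra.

    SNVs at contig edges (no full trinucleotide) are excluded and counted in
    ``n_excluded``. A REF allele that disagrees with the reference raises
    :class:`ReferenceMismatchError` listing the offending records.
    """
    seqs = _as_sequences(reference)
    counts6 = pd.Series(0, index=list(CLASSES6), dtype=int)
    counts96 = pd.Series(0, index=list(CHANNELS96), dtype=int)
    mismatches: list[str] = []
    n_excluded = 0
    for chrom, pos, ref, alt in snvs:
        if len(ref) != 1 or len(alt) != 1:
            continue  # spectra are defined for SNVs only
        seq = seqs[chrom]
        base = seq[pos - 1]
        if base != ref.upper():
            mismatches.append(f"{chrom}:{pos} ref={ref} reference={base}")
            continue
        if pos < 2 or pos > len(seq) - 1:
            n_excluded += 1
            continue
        tri = seq[pos - 2 : pos + 1]
        if "N" in tri:
            n_excluded += 1
            continue
        cls, channel = classify_snv(ref, alt, tri)
        counts6[cls] += 1
        counts96[channel] += 1
    if mismatches:
        raise ReferenceMismatchError(
            "REF mismatches at: " + "; ".join(mismatches[:20])
        )
    freq = reference_context_freq(seqs)
    normalized = (
        normalize96(counts96, freq)
        if counts96.sum() > 0
        else pd.Series(np.nan, index=list(CHANNELS96))
    )
    return SpectrumMatrix(
        counts6=counts6,
        counts96=counts96,
        ref_context_freq=freq,
        normalized96=normalized,
        n_excluded=n_excluded,
    )


def rainfall(snvs: Sequence[Snv]) -> pd.DataFrame:
    """Inter-mutation distances for rainfall plots.

    Returns one row per SNV with the distance to the previous SNV on the same
    chromosome (NaN for the first SNV of each chromosome) and the
    pyrimidine-collapsed substitution class.
    """
    rows = []
    snvs = sorted(snvs, key=lambda s: (s[0], s[1]))
    prev_chrom, prev_pos = None, None
    for chrom, pos, ref, alt in snvs:
        dist = float(pos - prev_pos) if chrom == prev_chrom else np.nan
        r, a = ref.upper(), alt.upper()
        if r in ("G", "A"):
            r, a = COMPLEMENT[r], COMPLEMENT[a]
        rows.append((chrom, pos, dist, f"{r}>{a}"))
        prev_chrom, prev_pos = chrom, pos
    return pd.DataFrame(rows, columns=["chrom", "pos", "distance", "snv_class"])


@dataclass(frozen=True)
class ClusterWindow:
    """A maximal genomic window satisfying a (window_bp, min_snvs) cluster rule."""

    chrom: str
    start: int
    end: int
    n_snvs: int
    rule: tuple[int, int]


DEFAULT_CLUSTER_RULES = ((160, 8), (5000, 50))


def _merge_spans(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def detect_clusters(
    snvs: Sequence[Snv],
    rules: Sequence[tuple[int, int]] = DEFAULT_CLUSTER_RULES,
) -> list[ClusterWindow]:
    """Sliding-window SNV cluster detection.

    For each rule ``(window_bp, min_snvs)`` a span qualifies when at least
    ``min_snvs`` SNVs fall within ``window_bp`` consecutive bases. Qualifying
    spans are anchored on SNV positions and overlapping spans are merged into
    maximal windows (two-pointer sweep over position-sorted SNVs).
    """
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos, _, _ in sorted(snvs, key=lambda s: (s[0], s[1])):
        by_chrom.setdefault(chrom, []).append(pos)
    out: list[ClusterWindow] = []
    for window_bp, min_snvs in rules:
        for chrom, positions in by_chrom.items():
            pos = np.asarray(positions)
            spans: list[tuple[int, int]] = []
            j = 0
            for i in range(len(pos)):
                if j < i:
                    j = i
                while j + 1 < len(pos) and pos[j + 1] - pos[i] + 1 <= window_bp:
                    j += 1
                if j - i + 1 >= min_snvs:
                    spans.append((int(pos[i]), int(pos[j])))
            for start, end in _merge_spans(spans):
                n = int(np.sum((pos >= start) & (pos <= end)))
                out.append(
                    ClusterWindow(
                        chrom=chrom,
                        start=start,
                        end=end,
                        n_snvs=n,
                        rule=(window_bp, min_snvs),
                    )
                )
    out.sort(key=lambda w: (w.rule, w.chrom, w.start))
    return out


def windowed_coverage(
    coverage: Sequence[float] | np.ndarray,
    window: int = 150_000,
    step: int = 75_000,
    cap: float = 100.0,
) -> pd.DataFrame:
    """Mean coverage in sliding windows, capped at ``cap`` on export.

    ``coverage`` is a per-base depth track (index 0 = position 1). Windows are
    1-based inclusive [start, end]; the last, possibly short, window covers
    the track tail.
    """
    cov = np.asarray(coverage, dtype=float)
    rows = []
    start = 0
    n = len(cov)
    while start < n:
        end = min(start + window, n)
        mean = float(cov[start:end].mean())
        rows.append((start + 1, end, min(mean, cap)))
        if end == n:
            break
        start += step
    return pd.DataFrame(rows, columns=["start", "end", "mean_coverage"])
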