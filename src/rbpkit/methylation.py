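"""Promoter H3K27me3 calling from multi-sample ChIP-Seq peak files.

Putative promoters are the symmetric ±3 kb windows around each annotated TSS
(0-based half-open coordinates throughout, BED convention). For each sample,
coverage of FDR-passing peaks on each promoter window is the union overlap in
base pairs (overlapping peaks are not double-counted). A promoter "has a
peak" in a sample when that overlap reaches ``min_overlap_bp``; a gene is
called methylated when at least one of its promoter windows has a peak in at
least ``min_samples`` samples (the ≥3-of-9 consensus rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "PeakRecord",
    "TSSRecord",
    "MethylationCall",
    "make_promoters",
    "peak_overlap",
    "call_methylation",
]


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based, inclusive
    end: int  # exclusive

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PeakRecord:
    interval: GenomicInterval
    sample_id: str
    fdr_p: float | None = None  # absent means the input is pre-filtered

    def __post_init__(self) -> None:
        if self.fdr_p is not None and not (0 <= self.fdr_p <= 1):
            raise ValueError("fdr_p must lie in [0, 1]")


@dataclass(frozen=True)
class TSSRecord:
    gene_id: str
    chrom: str
    pos: int  # 0-based TSS coordinate
    strand: str = "+"  # retained for provenance; the window is symmetric

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("TSS position must be >= 0")


@dataclass
class MethylationCall:
    gene_id: str
    n_samples_with_peak: int
    samples: list[str]
    methylated: bool
    total_overlap_bp: dict[str, int]


def make_promoters(
    tss: Iterable[TSSRecord], flank: int = 3000
) -> list[tuple[str, GenomicInterval]]:
    """±flank windows around each TSS, clipped at the chromosome origin;
    a gene with several TSS gets several windows, all retained."""
    if flank <= 0:
        raise ValueError("flank must be positive")
    out = []
    for t in tss:
        start = max(0, t.pos - flank)
        out.append((t.gene_id, GenomicInterval(t.chrom, start, t.pos + flank)))
    return out


def _union_overlap(window: GenomicInterval, intervals: Sequence[tuple[int, int]]) -> int:
    """Base pairs of the window covered by the union of intervals (sweep)."""
    clipped = sorted(
        (max(s, window.start), min(e, window.end))
        for s, e in intervals
        if s < window.end and e > window.start
    )
    covered = 0
    cur_s = cur_e = None
    for s, e in clipped:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered


def peak_overlap(window: GenomicInterval, peaks: Iterable[PeakRecord]) -> int:
    """Union overlap (bp) between one promoter window and one sample's peaks.

    Peaks are expected pre-filtered to the window's chromosome and FDR cutoff
    (as in :func:`call_methylation`); any on other chromosomes are ignored.
    """
    ivals = [
        (p.interval.start, p.interval.end) for p in peaks if p.interval.chrom == window.chrom
    ]
    return _union_overlap(window, ivals)


def call_methylation(
    promoters: Sequence[tuple[str, GenomicInterval]],
    peak_sets: Mapping[str, Sequence[PeakRecord]],
    min_samples: int = 3,
    fdr_max: float = 0.05,
    min_overlap_bp: int = 1,
) -> list[MethylationCall]:
    """Call per-gene promoter methylation from per-sample peak collections.

    A gene is methylated iff some single promoter window has union overlap of
    at least ``min_overlap_bp`` with FDR-passing peaks in at least
    ``min_samples`` samples. Peaks lacking an FDR value are treated as
    pre-filtered. Calls are sorted by gene_id; results are invariant to peak
    order and to splitting a peak into abutting pieces.
    """
    if not promoters:
        raise ValueError("no promoter windows supplied")
    if not peak_sets:
        raise ValueError("no peak samples supplied")
    if min_samples > len(peak_sets):
        warnings.warn(
            f"min_samples={min_samples} exceeds the {len(peak_sets)} samples provided; "
            "nothing can be called methylated",
            stacklevel=2,
        )

    # pre-filter and index peaks by (sample, chrom)
    by_sample_chrom: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for sid, peaks in peak_sets.items():
        for p in peaks:
            if p.fdr_p is not None and not (p.fdr_p < fdr_max):
                continue
            by_sample_chrom.setdefault((sid, p.interval.chrom), []).append(
                (p.interval.start, p.interval.end)
            )

    sample_ids = sorted(peak_sets)
    per_gene: dict[str, dict[str, object]] = {}
    for gene_id, window in promoters:
        hit_samples: set[str] = set()
        overlaps: dict[str, int] = {}
        for sid in sample_ids:
            ivals = by_sample_chrom.get((sid, window.chrom), [])
            ov = _union_overlap(window, ivals)
            if ov > 0:
                overlaps[sid] = ov
            if ov >= min_overlap_bp:
                hit_samples.add(sid)
        entry = per_gene.setdefault(
            gene_id, {"best_hits": set(), "overlap": {s: 0 for s in sample_ids}}
        )
        # the ≥min_samples rule applies per window; the gene takes its best window
        if len(hit_samples) > len(entry["best_hits"]):
            entry["best_hits"] = hit_samples
        for sid, ov in overlaps.items():
            entry["overlap"][sid] = max(entry["overlap"][sid], ov)

    calls = []
    for gene_id in sorted(per_gene):
        hits = sorted(per_gene[gene_id]["best_hits"])
        calls.append(
            MethylationCall(
                gene_id=gene_id,
                n_samples_with_peak=len(hits),
                samples=hits,
                methylated=len(hits) >= min_samples,
                total_overlap_bp={
                    s: v for s, v in per_gene[gene_id]["overlap"].items() if v > 0
                },
            )
        )
    return calls
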