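"""3'UTR motif scanning and the permutation test for target-set enrichment.

The question: do the transcripts pulled down with an RNA-binding protein
(RIP-Seq targets) carry its binding motif in their 3'UTRs more often than
expected? The answer here follows a resampling design: compute the proportion
of target genes whose 3'UTR contains the motif, then repeatedly draw
target-sized gene subsets from the expressed background (without replacement)
and record the null proportions; the empirical p-value is the add-one
corrected tail probability, so it is never exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .rnacompete import MotifModel

__all__ = [
    "MotifQuery",
    "PermutationResult",
    "build_background",
    "scan_utr",
    "motif_proportion",
    "permutation_test",
]


@dataclass(frozen=True)
class MotifQuery:
    """Motif definition: exact 7-mer list (default, GCGCGGG) or a PFM with a
    log-odds threshold expressed as a fraction of the maximal score."""

    kmers: tuple[str, ...] = ("GCGCGGG",)
    pfm: MotifModel | None = None
    pfm_threshold: float = 0.8

    def __post_init__(self) -> None:
        if not self.kmers and self.pfm is None:
            raise ValueError("query needs at least one k-mer or a PFM")
        if not (0 < self.pfm_threshold <= 1):
            raise ValueError("pfm_threshold must be in (0, 1]")

    @property
    def mode(self) -> str:
        return "pfm" if self.pfm is not None else "kmer_list"


@dataclass
class PermutationResult:
    n_targets: int
    n_background: int
    observed_proportion: float
    null_mean: float
    null_sd: float
    null_histogram: tuple[list[int], list[float]]
    n_iterations: int
    empirical_p: float
    seed: int

    def to_dict(self) -> dict:
        counts, edges = self.null_histogram
        return {
            "n_targets": self.n_targets,
            "n_background": self.n_background,
            "observed_proportion": self.observed_proportion,
            "null_proportions": {
                "mean": self.null_mean,
                "sd": self.null_sd,
                "histogram_counts": counts,
                "histogram_edges": edges,
            },
            "n_iterations": self.n_iterations,
            "empirical_p": self.empirical_p,
            "seed": self.seed,
        }


def build_background(counts: pd.DataFrame, min_count: int = 2) -> list[str]:
    """Expressed-gene background: genes with count >= ``min_count`` in at
    least one sample. ``counts`` is a gene x sample table indexed by gene_id
    (or carrying a ``gene_id`` column). Returns a sorted, deduplicated list."""
    if "gene_id" in counts.columns:
        counts = counts.set_index("gene_id")
    if counts.empty:
        raise ValueError("empty count table")
    vals = counts.to_numpy()
    if (vals < 0).any():
        raise ValueError("counts must be non-negative")
    keep = (vals >= min_count).any(axis=1)
    return sorted(set(counts.index[keep]))


def _normalize_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _pfm_scan(seq: str, model: MotifModel, threshold: float) -> int:
    probs = model.normalized().to_numpy()
    with np.errstate(divide="ignore"):
        logodds = np.log2(probs / 0.25)
    max_score = logodds.max(axis=0).sum()
    cutoff = threshold * max_score
    base_idx = {b: i for i, b in enumerate("ACGU")}
    w = model.width
    hits = 0
    for s in range(len(seq) - w + 1):
        window = seq[s : s + w]
        score = 0.0
        ok = True
        for j, b in enumerate(window):
            i = base_idx.get(b)
            if i is None:  # N or other ambiguity never matches
                ok = False
                break
            score += logodds[i, j]
        if ok and np.isfinite(score) and score >= cutoff:
            hits += 1
    return hits


def scan_utr(seq: str, query: MotifQuery = MotifQuery()) -> tuple[bool, int]:
    """Scan one 3'UTR for the motif; T and U are equivalent, overlapping
    occurrences all count, and N never matches. Returns (has_motif, n_hits)."""
    rna = _normalize_rna(seq)
    if query.mode == "pfm":
        n = _pfm_scan(rna, query.pfm, query.pfm_threshold)
        return n > 0, n
    n = 0
    for kmer in query.kmers:
        target = _normalize_rna(kmer)
        w = len(target)
        for s in range(len(rna) - w + 1):
            if rna[s : s + w] == target:
                n += 1
    return n > 0, n


def _presence_map(
    genes: Sequence[str],
    utrs: Mapping[str, str | Sequence[str]],
    query: MotifQuery,
) -> tuple[list[str], np.ndarray]:
    """Per-gene motif presence; a gene has the motif if any of its UTR
    isoforms matches. Genes without any UTR are dropped with a warning."""
    kept, present = [], []
    missing = 0
    for g in genes:
        seqs = utrs.get(g)
        if seqs is None:
            missing += 1
            continue
        if isinstance(seqs, str):
            seqs = [seqs]
        kept.append(g)
        present.append(any(scan_utr(s, query)[0] for s in seqs))
    if missing:
        warnings.warn(f"{missing} genes lack a 3'UTR and were dropped", stacklevel=3)
    return kept, np.asarray(present, dtype=bool)


def motif_proportion(
    genes: Sequence[str],
    utrs: Mapping[str, str | Sequence[str]],
    query: MotifQuery = MotifQuery(),
) -> float:
    """Fraction of genes whose 3'UTR (any isoform) contains the motif."""
    if len(genes) == 0:
        raise ValueError("empty gene list")
    kept, present = _presence_map(genes, utrs, query)
    if not kept:
        raise ValueError("no gene has a 3'UTR sequence")
    return float(present.mean())


def permutation_test(
    targets: Sequence[str],
    background: Sequence[str],
    utrs: Mapping[str, str | Sequence[str]],
    query: MotifQuery = MotifQuery(),
    n_iterations: int = 10_000,
    seed: int = 0,
    histogram_bins: int = 20,
) -> PermutationResult:
    """Permutation enrichment test of motif presence among target genes.

    Each of ``n_iterations`` iterations draws ``len(targets)`` genes without
    replacement from the background and records the null motif proportion.
    The empirical p is add-one corrected: (1 + #{null >= observed}) /
    (n_iterations + 1). Fully reproducible for a given seed.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    bg = list(dict.fromkeys(background))
    target_set = set(targets)
    if not target_set:
        raise ValueError("empty target list")
    if not target_set <= set(bg):
        raise ValueError("targets must be a subset of the background")

    bg_kept, bg_present = _presence_map(bg, utrs, query)
    index = {g: i for i, g in enumerate(bg_kept)}
    tgt_idx = [index[g] for g in targets if g in index]
    if not tgt_idx:
        raise ValueError("no target has a 3'UTR sequence")
    observed = float(bg_present[tgt_idx].mean())

    rng = np.random.default_rng(seed)
    m, n_bg = len(tgt_idx), len(bg_kept)
    null = np.empty(n_iterations, dtype=float)
    # uniform m-subsets via the m smallest of n_bg iid uniform keys, batched
    batch = max(1, min(n_iterations, int(5e6) // max(n_bg, 1)))
    done = 0
    while done < n_iterations:
        b = min(batch, n_iterations - done)
        keys = rng.random((b, n_bg))
        idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
        null[done : done + b] = bg_present[idx].mean(axis=1)
        done += b

    exceed = int(np.sum(null >= observed - 1e-12))
    p = (1 + exceed) / (n_iterations + 1)
    counts, edges = np.histogram(null, bins=histogram_bins, range=(0.0, 1.0))
    return PermutationResult(
        n_targets=m,
        n_background=n_bg,
        observed_proportion=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if n_iterations > 1 else 0.0,
        null_histogram=(counts.tolist(), edges.tolist()),
        n_iterations=n_iterations,
        empirical_p=float(p),
        seed=seed,
    )
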