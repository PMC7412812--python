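"""K-mer scoring of probe hybridization intensities and motif assembly.

Given per-probe microarray intensities from an RNAcompete-style pulldown, each
7-mer is scored by the trimmed mean of the log intensities of the probes that
contain it; scores are standardized across the 7-mer population into one-sided
Z-scores (only positive Z is interpreted as binding). The top-scoring 7-mers
are stacked into a position-frequency matrix whose consensus is the derived
binding motif — the route by which a GC-rich heptamer such as GCGCGGG emerges
from a pulldown in which its carrier probes light up.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from ._kmers import RNA_ALPHABET, code_to_kmer, encode, rolling_codes

__all__ = ["KmerScore", "MotifModel", "kmer_zscores", "top_kmer_pfm"]


@dataclass
class KmerScore:
    kmer: str
    set_label: str
    raw_score: float
    z: float
    n_probes: int


@dataclass
class MotifModel:
    """Ungapped position-frequency matrix over the RNA alphabet."""

    width: int
    pfm: pd.DataFrame  # rows A,C,G,U; columns 0..width-1; counts
    consensus: str

    def normalized(self) -> pd.DataFrame:
        return self.pfm / self.pfm.sum(axis=0)


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"probe_id", "set_label", "intensity"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"intensity table missing columns {sorted(missing)}")
    if table["probe_id"].duplicated().any():
        raise ValueError("duplicate probe_ids in intensity table")
    vals = table["intensity"].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
        raise ValueError("intensities must be finite and > 0")
    return table


def kmer_zscores(
    table: pd.DataFrame,
    pool_seqs: Mapping[str, str],
    k: int = 7,
    min_probes: int = 10,
    trim: float = 0.05,
) -> pd.DataFrame:
    """Score every k-mer with enough probe support, per set and combined.

    Parameters
    ----------
    table
        Columns ``probe_id``, ``set_label`` (A/B), ``intensity`` (> 0).
    pool_seqs
        probe_id -> variable-region sequence (DNA or RNA; U reads as T).
    min_probes
        A k-mer is scored only when at least this many probes contain it.
    trim
        Fraction trimmed from each tail of the log-intensity distribution
        before taking the mean (two-sided 5% trim by default).

    Returns
    -------
    DataFrame with columns kmer (RNA alphabet), set_label (A/B/combined),
    raw_score, z, n_probes, sorted by z descending within each set. Z is the
    raw score standardized across the scored k-mer population; if the raw
    scores are constant the Z-scores are all zero.
    """
    table = _validate_table(table)
    if len(table) < 2:
        raise ValueError("need at least two probes to score k-mers")
    missing = [p for p in table["probe_id"] if p not in pool_seqs]
    if missing:
        raise ValueError(f"{len(missing)} probe_ids lack sequences (e.g. {missing[:3]})")

    probe_ids = table["probe_id"].tolist()
    log_int = np.log(table["intensity"].to_numpy(dtype=float))
    labels = table["set_label"].to_numpy()

    # (k-mer code, probe index) pairs; presence, not multiplicity
    pair_codes, pair_probes = [], []
    for i, pid in enumerate(probe_ids):
        codes = np.unique(rolling_codes(encode(pool_seqs[pid]), k))
        pair_codes.append(codes)
        pair_probes.append(np.full(codes.size, i))
    all_codes = np.concatenate(pair_codes)
    all_probes = np.concatenate(pair_probes)

    rows = []
    for scope in ("A", "B", "combined"):
        member = np.ones(len(probe_ids), dtype=bool) if scope == "combined" else labels == scope
        if not member.any():
            continue
        sel = member[all_probes]
        codes = all_codes[sel]
        vals = log_int[all_probes[sel]]
        # per-group two-sided trimmed means via sorted cumulative sums
        order = np.lexsort((vals, codes))
        codes_s, vals_s = codes[order], vals[order]
        uniq, first, counts = np.unique(codes_s, return_index=True, return_counts=True)
        keep = counts >= min_probes
        if int(keep.sum()) < 2:
            raise ValueError(f"fewer than two scoreable {k}-mers in scope {scope}")
        g = (trim * counts).astype(int)  # elements cut from each tail
        cums = np.concatenate([[0.0], np.cumsum(vals_s)])
        raw = (cums[first + counts - g] - cums[first + g]) / (counts - 2 * g)
        raw, uniq, counts = raw[keep], uniq[keep], counts[keep]
        sd = raw.std(ddof=1)
        # guard against pure floating jitter on constant raw scores
        degenerate = sd <= 1e-12 * max(1.0, float(np.abs(raw).max()))
        z = np.zeros_like(raw) if degenerate else (raw - raw.mean()) / sd
        for code, r, zz, n in zip(uniq, raw, z, counts):
            rows.append(
                {
                    "kmer": code_to_kmer(int(code), k, rna=True),
                    "set_label": scope,
                    "raw_score": float(r),
                    "z": float(zz),
                    "n_probes": int(n),
                }
            )
    out = pd.DataFrame(rows)
    return out.sort_values(["set_label", "z"], ascending=[True, False]).reset_index(drop=True)


def top_kmer_pfm(scores: pd.DataFrame, top_n: int = 10, set_label: str = "combined") -> MotifModel:
    """Stack the ``top_n`` k-mers by Z into a position-frequency matrix.

    K-mers are aligned ungapped at offset 0. The consensus takes the
    column-wise argmax, ties broken by alphabet order (A < C < G < U).
    """
    sub = scores[scores["set_label"] == set_label].sort_values(
        ["z", "kmer"], ascending=[False, True]
    )
    if len(sub) < top_n:
        raise ValueError(f"only {len(sub)} scored k-mers; need {top_n}")
    top = sub.head(top_n)["kmer"].tolist()
    width = len(top[0])
    if any(len(m) != width for m in top):
        raise ValueError("top k-mers have unequal widths")
    pfm = pd.DataFrame(0, index=list(RNA_ALPHABET), columns=range(width), dtype=float)
    for m in top:
        for j, base in enumerate(m):
            pfm.loc[base, j] += 1
    consensus = "".join(pfm[j].idxmax() for j in range(width))
    return MotifModel(width=width, pfm=pfm, consensus=consensus)
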