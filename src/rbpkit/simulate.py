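"""Seeded synthetic-data generators with serialized ground truth.

Every pipeline input — 3'UTR FASTA with planted motifs, per-sample ChIP peak
files with planted methylated promoters, DE tables with planted up/down sets,
probe intensity tables with a spiked high-affinity 7-mer, one-site binding
titrations, and metabolite tables with planted dilution factors, group
effects and QC variability — can be generated here with known truth, so each
downstream stage is testable without any external download. All randomness
flows through numpy's PCG64 generator seeded explicitly; the same seed gives
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._kmers import DNA_ALPHABET
from .genesets import bh_adjust
from .methylation import GenomicInterval, PeakRecord, TSSRecord
from .pool import ProbePool
from .quant import fp_one_site

__all__ = [
    "SimTruth",
    "sim_transcriptome",
    "sim_peaks",
    "sim_de_table",
    "sim_fp",
    "sim_metabolites",
    "sim_intensities",
]


@dataclass
class SimTruth:
    """Ground-truth record serialized alongside every generated dataset."""

    generator: str
    seed: int
    params: dict
    truth: dict

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True, default=_jsonable)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _random_seq(rng: np.random.Generator, length: int, gc_content: float) -> str:
    p_gc = gc_content / 2
    p_at = (1 - gc_content) / 2
    codes = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at])
    return "".join(DNA_ALPHABET[c] for c in codes)


def _motif_free_seq(rng, length, gc_content, motif_dna: str, max_tries: int = 200) -> str:
    for _ in range(max_tries):
        s = _random_seq(rng, length, gc_content)
        if motif_dna not in s:
            return s
    raise RuntimeError("rejection sampling failed to produce a motif-free sequence")


# ---------------------------------------------------------------------------


def sim_transcriptome(
    n_genes: int = 1000,
    utr_len_range: tuple[int, int] = (200, 1500),
    gc_content: float = 0.5,
    n_targets: int = 100,
    spike_rate_targets: float = 0.4,
    spike_rate_background: float = 0.1,
    motif: str = "GCGCGGG",
    seed: int = 0,
) -> tuple[dict[str, str], list[str], pd.DataFrame, SimTruth]:
    """Synthetic transcriptome for the 3'UTR enrichment test.

    Every 3'UTR is generated motif-free by rejection sampling, then the motif
    is planted at a uniform position with probability ``spike_rate_targets``
    for the designated target genes and ``spike_rate_background`` for the
    rest, so per-gene motif presence is exactly Bernoulli at the stated
    rates. The accompanying count table makes ``build_background`` recover
    exactly the full gene universe. Returns (utrs, targets, counts, truth).
    """
    if not (0 <= spike_rate_background <= 1 and 0 <= spike_rate_targets <= 1):
        raise ValueError("spike rates must lie in [0, 1]")
    if n_targets > n_genes:
        raise ValueError("more targets than genes")
    if utr_len_range[0] < len(motif):
        raise ValueError("UTRs shorter than the motif")
    rng = np.random.default_rng(seed)
    motif_dna = motif.upper().replace("U", "T")
    genes = [f"g{i:05d}" for i in range(n_genes)]
    targets = genes[:n_targets]
    target_set = set(targets)

    utrs: dict[str, str] = {}
    planted: dict[str, bool] = {}
    for g in genes:
        length = int(rng.integers(utr_len_range[0], utr_len_range[1] + 1))
        seq = _motif_free_seq(rng, length, gc_content, motif_dna)
        rate = spike_rate_targets if g in target_set else spike_rate_background
        has = bool(rng.random() < rate)
        if has:
            pos = int(rng.integers(0, length - len(motif_dna) + 1))
            seq = seq[:pos] + motif_dna + seq[pos + len(motif_dna) :]
        utrs[g] = seq
        planted[g] = has

    counts = pd.DataFrame(
        {"s1": np.full(n_genes, 5), "s2": np.full(n_genes, 3)}, index=pd.Index(genes, name="gene_id")
    )
    truth = SimTruth(
        generator="sim_transcriptome",
        seed=seed,
        params={
            "n_genes": n_genes,
            "utr_len_range": list(utr_len_range),
            "gc_content": gc_content,
            "n_targets": n_targets,
            "spike_rate_targets": spike_rate_targets,
            "spike_rate_background": spike_rate_background,
            "motif": motif,
        },
        truth={
            "targets": targets,
            "genes_with_motif": sorted(g for g, h in planted.items() if h),
        },
    )
    return utrs, targets, counts, truth


def sim_peaks(
    n_samples: int = 9,
    chrom_len: int = 1_000_000,
    tss_count: int = 50,
    methylated_gene_fraction: float = 0.3,
    k_samples_per_methylated_gene: int = 3,
    peak_width_range: tuple[int, int] = (500, 2000),
    decoy_peaks_per_sample: int = 20,
    flank: int = 3000,
    seed: int = 0,
    chrom: str = "chr1",
) -> tuple[list[TSSRecord], dict[str, list[PeakRecord]], SimTruth]:
    """Per-sample peak collections with planted methylated promoters.

    Planted genes receive a peak overlapping their promoter window in exactly
    ``k_samples_per_methylated_gene`` samples; decoy peaks never overlap any
    promoter window. TSS are spaced so promoter windows are disjoint.
    """
    if k_samples_per_methylated_gene > n_samples:
        raise ValueError("k exceeds the number of samples")
    spacing = 2 * flank + max(peak_width_range) + 1000
    if tss_count * spacing + flank > chrom_len:
        raise ValueError("promoter windows exceed the toy chromosome")
    rng = np.random.default_rng(seed)

    tss = [
        TSSRecord(gene_id=f"g{i:04d}", chrom=chrom, pos=flank + i * spacing, strand="+")
        for i in range(tss_count)
    ]
    n_meth = int(round(methylated_gene_fraction * tss_count))
    meth_idx = sorted(rng.choice(tss_count, size=n_meth, replace=False).tolist())
    meth_genes = [tss[i].gene_id for i in meth_idx]

    sample_ids = [f"s{j+1}" for j in range(n_samples)]
    peak_sets: dict[str, list[PeakRecord]] = {s: [] for s in sample_ids}
    for i in meth_idx:
        t = tss[i]
        chosen = rng.choice(n_samples, size=k_samples_per_methylated_gene, replace=False)
        for j in chosen:
            width = int(rng.integers(peak_width_range[0], peak_width_range[1] + 1))
            lo = max(0, t.pos - flank)
            start = int(rng.integers(lo, t.pos + flank - 1))
            peak_sets[sample_ids[j]].append(
                PeakRecord(
                    interval=GenomicInterval(chrom, start, start + width),
                    sample_id=sample_ids[j],
                    fdr_p=float(rng.uniform(0, 0.049)),
                )
            )

    # decoys: confined to the gap regions beyond every promoter window
    promoter_spans = [(max(0, t.pos - flank), t.pos + flank) for t in tss]
    for sid in sample_ids:
        placed = 0
        while placed < decoy_peaks_per_sample:
            width = int(rng.integers(peak_width_range[0], peak_width_range[1] + 1))
            start = int(rng.integers(0, chrom_len - width))
            if any(start < e and start + width > s for s, e in promoter_spans):
                continue
            peak_sets[sid].append(
                PeakRecord(
                    interval=GenomicInterval(chrom, start, start + width),
                    sample_id=sid,
                    fdr_p=float(rng.uniform(0, 0.049)),
                )
            )
            placed += 1

    truth = SimTruth(
        generator="sim_peaks",
        seed=seed,
        params={
            "n_samples": n_samples,
            "chrom_len": chrom_len,
            "tss_count": tss_count,
            "methylated_gene_fraction": methylated_gene_fraction,
            "k_samples_per_methylated_gene": k_samples_per_methylated_gene,
            "peak_width_range": list(peak_width_range),
            "decoy_peaks_per_sample": decoy_peaks_per_sample,
            "flank": flank,
        },
        truth={"methylated_genes": meth_genes},
    )
    return tss, peak_sets, truth


def sim_de_table(
    n_genes: int = 2000,
    frac_up: float = 0.05,
    frac_down: float = 0.05,
    lfc_effect: float = 2.0,
    n_reps: int = 3,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Differential-expression result table with planted up/down genes.

    Per gene, replicate log2 expression is drawn N(base, noise_sd) in the
    control group and N(base ± lfc_effect, noise_sd) in the treated group for
    planted genes; log2FoldChange is the mean difference, p from a Welch
    t-test across replicates, padj by BH. Emulates the shape of a DESeq2
    output table for threshold-filter testing, not its estimator.
    """
    if frac_up + frac_down > 1:
        raise ValueError("planted fractions exceed 1")
    if n_reps < 2:
        raise ValueError("need at least 2 replicates per group")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    n_up = int(round(frac_up * n_genes))
    n_down = int(round(frac_down * n_genes))
    effects = np.zeros(n_genes)
    effects[:n_up] = lfc_effect
    effects[n_up : n_up + n_down] = -lfc_effect

    base = rng.normal(8, 2, size=n_genes)
    ctrl = rng.normal(base[:, None], noise_sd, size=(n_genes, n_reps))
    trt = rng.normal((base + effects)[:, None], noise_sd, size=(n_genes, n_reps))
    lfc = trt.mean(axis=1) - ctrl.mean(axis=1)
    _, p = stats.ttest_ind(trt, ctrl, axis=1, equal_var=False)
    table = pd.DataFrame(
        {"gene_id": genes, "log2FoldChange": lfc, "pvalue": p, "padj": bh_adjust(p)}
    )
    truth = SimTruth(
        generator="sim_de_table",
        seed=seed,
        params={
            "n_genes": n_genes,
            "frac_up": frac_up,
            "frac_down": frac_down,
            "lfc_effect": lfc_effect,
            "n_reps": n_reps,
            "noise_sd": noise_sd,
        },
        truth={"up_genes": genes[:n_up], "down_genes": genes[n_up : n_up + n_down]},
    )
    return table, truth


def sim_fp(
    kd: float = 47.0,
    fp0: float = 60.0,
    fpmax: float = 160.0,
    conc_grid: Sequence[float] = (0, 5, 10, 25, 50, 100, 250, 500, 1000),
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """One-site binding titration from the closed form plus Gaussian noise.

    The default truth (Kd 47 nM on a 0-1000 nM protein grid) mirrors a
    high-affinity protein/7-mer interaction measured by fluorescence
    polarization; each grid point is read in triplicate, as plate readers
    typically are.
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    grid = np.asarray(conc_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty concentration grid")
    rng = np.random.default_rng(seed)
    conc = np.tile(grid, n_replicates)
    clean = fp_one_site(conc, kd, fp0, fpmax)
    fp = clean + rng.normal(0, noise_sd, size=conc.size) if noise_sd > 0 else clean
    table = pd.DataFrame({"conc_nM": conc, "fp": fp})
    truth = SimTruth(
        generator="sim_fp",
        seed=seed,
        params={
            "conc_grid": grid.tolist(),
            "noise_sd": noise_sd,
            "n_replicates": n_replicates,
        },
        truth={"kd": kd, "fp0": fp0, "fpmax": fpmax},
    )
    return table, truth


def sim_metabolites(
    n_features: int = 200,
    n_per_group: int = 5,
    n_qc: int = 5,
    dilution_factors: Sequence[float] | None = None,
    n_effect_features: int = 20,
    log2_fold_change: float = 1.0,
    high_cv_fraction: float = 0.1,
    high_cv: float = 0.35,
    base_cv: float = 0.05,
    group_noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str], SimTruth]:
    """Metabolite feature table with planted dilution, effects and QC noise.

    QC columns get multiplicative noise rescaled to an exact per-feature
    sample CV (``base_cv`` for stable features, ``high_cv`` for the planted
    unstable fraction), so the 25% filter has a deterministic pass/fail
    truth. Group samples carry the planted log2 fold change on the effect
    features; every sample column is then multiplied by its dilution factor.
    Returns (table, sample roles, truth).
    """
    rng = np.random.default_rng(seed)
    features = [f"m{i:04d}" for i in range(n_features)]
    base = rng.lognormal(mean=10, sigma=1, size=n_features)

    n_high = int(round(high_cv_fraction * n_features))
    cv_target = np.full(n_features, base_cv)
    cv_target[:n_high] = high_cv

    qc_cols = [f"QC{j+1}" for j in range(n_qc)]
    ctrl_cols = [f"ctrl{j+1}" for j in range(n_per_group)]
    kd_cols = [f"kd{j+1}" for j in range(n_per_group)]
    columns = qc_cols + ctrl_cols + kd_cols
    if dilution_factors is None:
        dilution = {c: 1.0 for c in columns}
    else:
        if len(dilution_factors) != len(columns):
            raise ValueError(f"need {len(columns)} dilution factors")
        dilution = dict(zip(columns, map(float, dilution_factors)))

    # QC: multiplicative noise standardized to the exact target CV per feature
    qc_noise = rng.normal(0, 1, size=(n_features, n_qc))
    m = qc_noise.mean(axis=1, keepdims=True)
    s = qc_noise.std(axis=1, ddof=1, keepdims=True)
    s[s == 0] = 1.0
    qc_vals = base[:, None] * (1 + cv_target[:, None] * (qc_noise - m) / s)

    effect = np.zeros(n_features)
    effect[n_high : n_high + n_effect_features] = log2_fold_change
    ctrl_vals = base[:, None] * rng.lognormal(0, group_noise_sd, size=(n_features, n_per_group))
    kd_vals = (base * 2.0**effect)[:, None] * rng.lognormal(
        0, group_noise_sd, size=(n_features, n_per_group)
    )

    table = pd.DataFrame(
        np.hstack([qc_vals, ctrl_vals, kd_vals]),
        index=pd.Index(features, name="feature"),
        columns=columns,
    )
    for c in columns:
        table[c] = table[c] * dilution[c]
    roles = {c: ("QC" if c in qc_cols else "control" if c in ctrl_cols else "knockdown") for c in columns}

    truth = SimTruth(
        generator="sim_metabolites",
        seed=seed,
        params={
            "n_features": n_features,
            "n_per_group": n_per_group,
            "n_qc": n_qc,
            "n_effect_features": n_effect_features,
            "log2_fold_change": log2_fold_change,
            "high_cv_fraction": high_cv_fraction,
            "high_cv": high_cv,
            "base_cv": base_cv,
            "group_noise_sd": group_noise_sd,
        },
        truth={
            "high_cv_features": features[:n_high],
            "effect_features": features[n_high : n_high + n_effect_features],
            "dilution_factors": dilution,
        },
    )
    return table, roles, truth


def sim_intensities(
    pool: ProbePool | Mapping[str, str],
    set_labels: Mapping[str, str] | None = None,
    spiked_kmer: str = "GCGCGGG",
    effect_multiplier: float = 10.0,
    noise_sd: float = 0.25,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Probe intensity table emulating a pulldown hybridization readout.

    Baseline intensities are lognormal; probes whose variable region contains
    the spiked 7-mer (DNA space) are multiplied by ``effect_multiplier``.
    """
    if len(spiked_kmer) != 7:
        raise ValueError("spiked k-mer must have length 7")
    if isinstance(pool, ProbePool):
        seqs = pool.sequences_by_id()
        labels = {
            pid: (str(pool.set_labels[i]) if pool.set_labels is not None else ("A", "B")[i % 2])
            for i, pid in enumerate(pool.ids)
        }
    else:
        seqs = dict(pool)
        if set_labels is None:
            labels = {pid: ("A", "B")[i % 2] for i, pid in enumerate(seqs)}
        else:
            labels = dict(set_labels)
    rng = np.random.default_rng(seed)
    kmer_dna = spiked_kmer.upper().replace("U", "T")
    ids = list(seqs)
    carrier = np.array([kmer_dna in seqs[p].upper().replace("U", "T") for p in ids])
    if not carrier.any():
        import warnings

        warnings.warn(f"spiked k-mer {spiked_kmer} absent from the pool", stacklevel=2)
    intensity = rng.lognormal(mean=5, sigma=noise_sd, size=len(ids))
    intensity[carrier] *= effect_multiplier
    table = pd.DataFrame(
        {"probe_id": ids, "set_label": [labels[p] for p in ids], "intensity": intensity}
    )
    truth = SimTruth(
        generator="sim_intensities",
        seed=seed,
        params={
            "spiked_kmer": spiked_kmer,
            "effect_multiplier": effect_multiplier,
            "noise_sd": noise_sd,
        },
        truth={"n_carrier_probes": int(carrier.sum())},
    )
    return table, truth
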