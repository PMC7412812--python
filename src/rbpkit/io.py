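"""File-format boundaries: FASTA, BED-like peaks, TSV tables, JSON reports."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .methylation import GenomicInterval, PeakRecord, TSSRecord
from .pool import KmerCoverageReport, ProbePool


def write_pool_fasta(pool: ProbePool, path) -> None:
    """RNA FASTA of the designed pool; headers are ``probe_id|set|start``."""
    with open(path, "w") as fh:
        for rec in pool:
            seq = rec.rna_seq if rec.rna_seq is not None else rec.variable_seq
            fh.write(f">{rec.probe_id}|{rec.set_label or '.'}|{rec.start}\n{seq}\n")


def write_pool_manifest(pool: ProbePool, path) -> None:
    pd.DataFrame(
        [
            {
                "probe_id": r.probe_id,
                "set_label": r.set_label,
                "start": r.start,
                "variable_seq": r.variable_seq,
                "rna_seq": r.rna_seq,
            }
            for r in pool
        ]
    ).to_csv(path, sep="\t", index=False)


def read_fasta(path) -> dict[str, str]:
    """FASTA -> {record id (first |-field): sequence}."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id.split("|")[0]] = str(rec.seq)
    return out


def read_pool_fasta(path) -> tuple[dict[str, str], dict[str, str]]:
    """Designed-pool FASTA -> (sequences by probe_id, set labels by probe_id)."""
    seqs: dict[str, str] = {}
    labels: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.id.split("|")
        seqs[fields[0]] = str(rec.seq)
        labels[fields[0]] = fields[1] if len(fields) > 1 else "."
    return seqs, labels


def reports_to_json(reports: Iterable[KmerCoverageReport], path=None) -> str:
    payload = [dataclasses.asdict(r) for r in reports]
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def read_bed_peaks(
    path, sample_id: str, chrom_col: int = 0, q_dialect: str | None = None
) -> list[PeakRecord]:
    """BED/narrowPeak -> peak records for one sample.

    ``q_dialect`` controls column 9 of narrowPeak input: ``"neglog10"`` reads
    it as -log10(q), ``"raw"`` as the q-value itself, ``None`` ignores it
    (peaks treated as pre-filtered).
    """
    peaks: list[PeakRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[chrom_col], int(parts[1]), int(parts[2])
            fdr = None
            if q_dialect is not None and len(parts) > 8:
                q = float(parts[8])
                fdr = 10.0 ** (-q) if q_dialect == "neglog10" else q
            peaks.append(
                PeakRecord(interval=GenomicInterval(chrom, start, end), sample_id=sample_id, fdr_p=fdr)
            )
    return peaks


def write_bed(intervals: Iterable[tuple[str, GenomicInterval]], path) -> None:
    with open(path, "w") as fh:
        for name, iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def read_tss_table(path, one_based: bool = False) -> list[TSSRecord]:
    """TSS TSV with columns gene_id, chrom, pos, strand."""
    df = pd.read_csv(path, sep="\t")
    offset = 1 if one_based else 0
    return [
        TSSRecord(
            gene_id=str(r.gene_id), chrom=str(r.chrom), pos=int(r.pos) - offset, strand=str(r.strand)
        )
        for r in df.itertuples()
    ]


def write_utr_fasta(utrs: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for gene, seq in utrs.items():
            fh.write(f">{gene}\n{seq}\n")


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
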