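"""Differential-expression threshold filters and gene-set integration.

DE estimation itself happens upstream (DESeq2-style tables are consumed as
finished input); this module applies the printed threshold rules — |log2FC|
>= 1 with BH-adjusted p < 0.05 for knockdown RNA-Seq, log2FC >= 0.5 with
adjusted p < 0.05 for RIP-Seq association — and integrates the resulting
named sets: which knockdown-upregulated genes are also repressed in tumors
and carry promoter H3K27me3. Fold-change bounds are inclusive, FDR bounds
strict, exactly as printed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSet",
    "OverlapResult",
    "bh_adjust",
    "filter_de",
    "integrate_sets",
    "overlap_test",
]


@dataclass
class GeneSet:
    name: str
    genes: frozenset[str]
    provenance: str

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.provenance:
            raise ValueError("provenance must be non-empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class OverlapResult:
    set_a: str
    set_b: str
    universe_size: int
    size_a: int
    size_b: int
    intersection: int
    hypergeometric_p: float
    fold_enrichment: float


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (same order as the input)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _strip_versions(genes: pd.Series) -> pd.Series:
    return genes.str.replace(r"\.\d+$", "", regex=True)


def filter_de(
    table: pd.DataFrame,
    min_abs_lfc: float,
    max_fdr: float = 0.05,
    direction: str = "both",
    name: str | None = None,
    strip_versions: bool = False,
) -> GeneSet:
    """Apply a printed DE threshold rule to a gene-level result table.

    ``table`` needs columns ``gene_id``, ``log2FoldChange`` and ``padj`` (or
    ``pvalue``, from which ``padj`` is computed by BH). A gene passes when its
    adjusted p is strictly below ``max_fdr`` and its fold change clears
    ``min_abs_lfc`` inclusively in the requested direction (up / down / both).
    """
    if direction not in ("up", "down", "both"):
        raise ValueError("direction must be 'up', 'down' or 'both'")
    cols = set(table.columns)
    if "gene_id" not in cols or "log2FoldChange" not in cols:
        raise ValueError("table needs gene_id and log2FoldChange columns")
    if table["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_ids in DE table")
    if "padj" in cols and table["padj"].notna().any():
        padj = table["padj"].to_numpy(dtype=float)
    elif "pvalue" in cols:
        padj = bh_adjust(table["pvalue"].to_numpy(dtype=float))
    else:
        raise ValueError("table needs a padj or pvalue column")

    lfc = table["log2FoldChange"].to_numpy(dtype=float)
    if direction == "up":
        fc_pass = lfc >= min_abs_lfc
    elif direction == "down":
        fc_pass = lfc <= -min_abs_lfc
    else:
        fc_pass = np.abs(lfc) >= min_abs_lfc
    keep = fc_pass & (padj < max_fdr)

    genes = table.loc[keep, "gene_id"]
    if strip_versions:
        genes = _strip_versions(genes)
    label = name or f"{direction}_lfc{min_abs_lfc}_fdr{max_fdr}"
    return GeneSet(
        name=label,
        genes=frozenset(genes),
        provenance=f"{direction}: |log2FC| >= {min_abs_lfc} (inclusive), padj < {max_fdr} (strict)",
    )


def integrate_sets(
    up_in_kd: GeneSet,
    methylated: GeneSet,
    gbm_down_vs_lgg: GeneSet,
    gbm_down_vs_cortex: GeneSet,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotate each knockdown-upregulated gene with membership flags.

    Returns (per-gene annotation table, flag-combination counts). Flags:
    ``down_vs_lgg``, ``down_vs_cortex``, ``h3k27me3``.
    """
    rows = []
    for g in sorted(up_in_kd.genes):
        rows.append(
            {
                "gene_id": g,
                "down_vs_lgg": g in gbm_down_vs_lgg.genes,
                "down_vs_cortex": g in gbm_down_vs_cortex.genes,
                "h3k27me3": g in methylated.genes,
            }
        )
    table = pd.DataFrame(rows, columns=["gene_id", "down_vs_lgg", "down_vs_cortex", "h3k27me3"])
    if table.empty:
        summary = pd.DataFrame(columns=["down_vs_lgg", "down_vs_cortex", "h3k27me3", "n_genes"])
    else:
        summary = (
            table.groupby(["down_vs_lgg", "down_vs_cortex", "h3k27me3"])
            .size()
            .rename("n_genes")
            .reset_index()
        )
    return table, summary


def overlap_test(a: GeneSet, b: GeneSet, universe: GeneSet) -> OverlapResult:
    """Hypergeometric upper-tail test of the overlap between two gene sets.

    p = P[X >= |A∩B|] with X ~ Hypergeom(|U|, |A|, |B|); fold enrichment is
    (|A∩B|/|A|) / (|B|/|U|).
    """
    if len(universe) == 0:
        raise ValueError("empty universe")
    if not (a.genes <= universe.genes and b.genes <= universe.genes):
        raise ValueError("sets must be subsets of the universe")
    n_u, n_a, n_b = len(universe), len(a), len(b)
    inter = len(a.genes & b.genes)
    p = float(stats.hypergeom.sf(inter - 1, n_u, n_a, n_b)) if inter > 0 else 1.0
    expected = n_a * n_b / n_u
    fold = inter / expected if expected > 0 else float("nan")
    return OverlapResult(
        set_a=a.name,
        set_b=b.name,
        universe_size=n_u,
        size_a=n_a,
        size_b=n_b,
        intersection=inter,
        hypergeometric_p=min(1.0, p),
        fold_enrichment=fold,
    )
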