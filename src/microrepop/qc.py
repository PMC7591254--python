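"""Cell- and gene-level quality-control filters.

Cells are dropped when their total UMI count falls below 500 or above
20,000, when fewer than 200 genes are detected, or when mitochondrial genes
exceed 10% of counts; genes detected in fewer than 10 surviving cells are
then removed. All cell rules are evaluated jointly on the input matrix, so
their order does not matter; the gene rule runs after on the survivors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import CountMatrix


@dataclass
class QCThresholds:
    umi_min: int = 500
    umi_max: int = 20_000
    genes_min: int = 200
    mito_max: float = 0.10
    gene_min_cells: int = 10

    def __post_init__(self) -> None:
        if not self.umi_min < self.umi_max:
            raise ValueError("umi_min must be < umi_max")
        if not 0 < self.mito_max <= 1:
            raise ValueError("mito_max must be in (0, 1]")


@dataclass
class QCReport:
    n_cells_in: int
    n_cells_out: int
    n_genes_in: int
    n_genes_out: int
    removals: dict[str, int] = field(default_factory=dict)
    cell_stats: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "n_cells_in": self.n_cells_in,
            "n_cells_out": self.n_cells_out,
            "n_genes_in": self.n_genes_in,
            "n_genes_out": self.n_genes_out,
            "removals": dict(self.removals),
        }


def cell_stats(matrix: CountMatrix) -> pd.DataFrame:
    """Per-cell total UMI, detected-gene count, and mitochondrial fraction."""
    counts = matrix.counts.tocsc()
    total = np.asarray(counts.sum(axis=0)).ravel()
    n_detected = np.asarray((counts > 0).sum(axis=0)).ravel()
    mito_mask = matrix.gene_meta["is_mito"].to_numpy(dtype=bool)
    if mito_mask.any():
        mito_total = np.asarray(counts[mito_mask, :].sum(axis=0)).ravel()
    else:
        mito_total = np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mito = np.where(total > 0, mito_total / np.maximum(total, 1), 0.0)
    return pd.DataFrame(
        {
            "cell_id": matrix.cell_meta["cell_id"].to_numpy(),
            "total_umi": total.astype(int),
            "n_genes": n_detected.astype(int),
            "pct_mito": pct_mito,
        }
    )


def apply_qc(
    matrix: CountMatrix,
    thresholds: QCThresholds | None = None,
    cell_blacklist: list[str] | None = None,
) -> tuple[CountMatrix, QCReport]:
    """Filter a count matrix by the standard QC rules.

    Returns the filtered matrix and a report itemising removals per rule
    (a cell failing several rules is counted under each). ``cell_blacklist``
    removes named cells in addition to the threshold rules, for externally
    identified outliers.
    """
    thresholds = thresholds or QCThresholds()
    stats = cell_stats(matrix)
    n_cells_in = matrix.n_cells
    n_genes_in = matrix.n_genes

    if not matrix.gene_meta["is_mito"].any():
        warnings.warn(
            "no mitochondrial genes flagged; percent-mito rule passes vacuously"
        )

    total = stats["total_umi"].to_numpy()
    n_genes = stats["n_genes"].to_numpy()
    pct_mito = stats["pct_mito"].to_numpy()

    fail_umi_low = total < thresholds.umi_min
    fail_umi_high = total > thresholds.umi_max
    fail_genes = n_genes < thresholds.genes_min
    fail_mito = pct_mito > thresholds.mito_max
    fail_blacklist = np.zeros(n_cells_in, dtype=bool)
    if cell_blacklist:
        fail_blacklist = matrix.cell_meta["cell_id"].isin(cell_blacklist).to_numpy()

    keep_cells = ~(fail_umi_low | fail_umi_high | fail_genes | fail_mito | fail_blacklist)
    out = matrix.subset_cells(keep_cells)

    # Gene filter on surviving cells only.
    detected = np.asarray((out.counts > 0).sum(axis=1)).ravel()
    keep_genes = detected >= thresholds.gene_min_cells
    out = out.subset_genes(keep_genes)

    if out.n_cells == 0 and n_cells_in > 0:
        warnings.warn("all cells removed by QC")

    report = QCReport(
        n_cells_in=n_cells_in,
        n_cells_out=out.n_cells,
        n_genes_in=n_genes_in,
        n_genes_out=out.n_genes,
        removals={
            "umi_low": int(fail_umi_low.sum()),
            "umi_high": int(fail_umi_high.sum()),
            "few_genes": int(fail_genes.sum()),
            "high_mito": int(fail_mito.sum()),
            "blacklist": int(fail_blacklist.sum()),
            "genes_low_cells": int((~keep_genes).sum()),
        },
        cell_stats=stats,
    )
    return out, report
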