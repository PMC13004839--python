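"""Single-cell QC filtering and normalization.

Cells expressing fewer than ``min_genes_per_cell`` genes are dropped, then
genes detected in fewer than ``min_cells_per_gene`` cells, then cells whose
mitochondrial count fraction exceeds ``max_mito_fraction`` (strictly).  Counts
are then scaled per cell to a fixed target sum and log1p-transformed.  A gene
counts as "expressed"/"detected" in a cell when its count is > 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import ExpressionMatrix, GremnetError, ValidationError


@dataclass
class QCThresholds:
    min_genes_per_cell: int = 200
    min_cells_per_gene: int = 10
    max_mito_fraction: float = 0.15
    target_sum: float = 10000.0

    def __post_init__(self) -> None:
        if self.min_genes_per_cell <= 0 or self.min_cells_per_gene <= 0:
            raise ValidationError("QC thresholds must be positive")
        if not (0 < self.max_mito_fraction <= 1):
            raise ValidationError("max_mito_fraction must be in (0, 1]")
        if self.target_sum <= 0:
            raise ValidationError("target_sum must be positive")


@dataclass
class QCReport:
    """Per-step accounting of what the filters removed, in application order."""

    n_cells_in: int = 0
    n_genes_in: int = 0
    cells_removed_low_genes: int = 0
    genes_removed_low_cells: int = 0
    cells_removed_high_mito: int = 0
    n_cells_out: int = 0
    n_genes_out: int = 0
    removed_cell_ids: list = field(default_factory=list)
    removed_gene_ids: list = field(default_factory=list)


def qc_filter(
    x: ExpressionMatrix,
    mito_gene_ids: set[str] | None = None,
    thresholds: QCThresholds | None = None,
) -> tuple[ExpressionMatrix, QCReport]:
    """Apply the three QC filters in fixed order: cell gene-count, then gene
    cell-count, then cell mitochondrial fraction.

    Boundary semantics: a cell expressing exactly ``min_genes_per_cell`` genes
    is retained (strictly fewer removed); a gene detected in exactly
    ``min_cells_per_gene`` cells is retained; a cell at exactly
    ``max_mito_fraction`` is retained (strictly greater removed).
    """
    if x.layer != "counts":
        raise ValidationError("qc_filter requires a counts-layer matrix")
    t = thresholds or QCThresholds()
    mito = mito_gene_ids or set()

    report = QCReport(n_cells_in=x.n_samples, n_genes_in=x.n_genes)
    values = x.values
    cell_ids = np.array(x.sample_ids, dtype=object)
    gene_ids = np.array(x.gene_ids, dtype=object)

    # 1. cells expressing too few genes
    detected_per_cell = (values > 0).sum(axis=1)
    keep_cells = detected_per_cell >= t.min_genes_per_cell
    report.cells_removed_low_genes = int((~keep_cells).sum())
    report.removed_cell_ids.extend(cell_ids[~keep_cells].tolist())
    values, cell_ids = values[keep_cells], cell_ids[keep_cells]

    # 2. genes detected in too few cells
    cells_per_gene = (values > 0).sum(axis=0)
    keep_genes = cells_per_gene >= t.min_cells_per_gene
    report.genes_removed_low_cells = int((~keep_genes).sum())
    report.removed_gene_ids.extend(gene_ids[~keep_genes].tolist())
    values, gene_ids = values[:, keep_genes], gene_ids[keep_genes]

    # 3. cells with high mitochondrial fraction
    mito_mask = np.array([g in mito for g in gene_ids], dtype=bool)
    totals = values.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, values[:, mito_mask].sum(axis=1) / np.maximum(totals, 1e-300), 0.0)
    keep_cells2 = mito_frac <= t.max_mito_fraction
    report.cells_removed_high_mito = int((~keep_cells2).sum())
    report.removed_cell_ids.extend(cell_ids[~keep_cells2].tolist())
    values, cell_ids = values[keep_cells2], cell_ids[keep_cells2]

    if values.shape[0] == 0:
        raise GremnetError("QC filtering removed every cell")

    report.n_cells_out, report.n_genes_out = values.shape
    out = ExpressionMatrix(values, cell_ids.tolist(), gene_ids.tolist(), layer="counts")
    return out, report


def normalize_log1p(x: ExpressionMatrix, target_sum: float = 10000.0) -> ExpressionMatrix:
    """Scale each cell to ``target_sum`` total counts, then ln(1 + v)."""
    if x.layer != "counts":
        raise ValidationError("normalize_log1p requires a counts-layer matrix")
    totals = x.values.sum(axis=1)
    zero = np.nonzero(totals == 0)[0]
    if zero.size:
        raise ValidationError(
            f"cell {x.sample_ids[int(zero[0])]!r} has zero total count"
        )
    scaled = x.values * (target_sum / totals)[:, None]
    return ExpressionMatrix(
        np.log1p(scaled), list(x.sample_ids), list(x.gene_ids), layer="lognorm"
    )
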