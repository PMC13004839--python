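"""ATAC-RNA concordance classification.

Genes are labeled by the joint direction and significance of their expression
change (RNA) and the accessibility change of their best-associated peak
(ATAC).  Significance is inclusive at the thresholds: a gene is "up" when
padj <= alpha and log2fc >= lfc, "down" when padj <= alpha and
log2fc <= -lfc, otherwise not significant; a missing adjusted p-value is
never significant.  Defaults follow common bulk practice: RNA padj <= 0.05
with |log2FC| >= 0.25, ATAC FDR <= 0.05 with |log2FC| >= 0.1.

A lightweight Welch-t differential test with Benjamini-Hochberg adjustment is
included so fully synthetic runs need no external differential caller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import DiffRecord, ExpressionMatrix, GremnetError, ValidationError

LN2 = float(np.log(2.0))


@dataclass
class ConcordanceThresholds:
    rna_alpha: float = 0.05
    rna_lfc: float = 0.25
    atac_alpha: float = 0.05
    atac_lfc: float = 0.1

    def __post_init__(self) -> None:
        for a in (self.rna_alpha, self.atac_alpha):
            if not (0 < a <= 1):
                raise ValidationError("alpha thresholds must lie in (0, 1]")
        if self.rna_lfc < 0 or self.atac_lfc < 0:
            raise ValidationError("lfc thresholds must be >= 0")


@dataclass
class ConcordanceRecord:
    gene_id: str
    rna_state: str  # up | down | ns
    atac_state: str
    label: str
    best_peak_id: str | None = None


_LABELS = {
    ("up", "up"): "concordant_up",
    ("down", "down"): "concordant_down",
    ("up", "down"): "discordant",
    ("down", "up"): "discordant",
    ("up", "ns"): "expression_only",
    ("down", "ns"): "expression_only",
    ("ns", "up"): "accessibility_only",
    ("ns", "down"): "accessibility_only",
    ("ns", "ns"): "neither",
}


def simple_differential(
    x_a: ExpressionMatrix, x_b: ExpressionMatrix
) -> list[DiffRecord]:
    """Welch two-sample t-test per shared gene, group a versus group b.

    Inputs are natural-log expression; the reported log2fc is
    (mean_a - mean_b) / ln 2.  Genes with zero variance in both groups get
    p = 1.  P-values are BH-adjusted across all tested genes.
    """
    gb = {g: j for j, g in enumerate(x_b.gene_ids)}
    shared = [g for g in x_a.gene_ids if g in gb]
    if not shared:
        raise ValidationError("groups share no genes")
    if x_a.n_samples < 2 or x_b.n_samples < 2:
        raise ValidationError("need >= 2 samples per group")
    ai = [x_a.gene_ids.index(g) for g in shared]
    bi = [gb[g] for g in shared]
    va = x_a.values[:, ai]
    vb = x_b.values[:, bi]
    lfc = (va.mean(axis=0) - vb.mean(axis=0)) / LN2
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-constant genes trip scipy's precision-loss warning; they are
        # handled explicitly below (p set to 1)
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(va, vb, axis=0, equal_var=False)
        pvals = np.asarray(res.pvalue, dtype=float)
    both_flat = (va.var(axis=0) == 0) & (vb.var(axis=0) == 0)
    pvals = np.where(np.isnan(pvals) | both_flat, 1.0, pvals)
    padj = multipletests(pvals, method="fdr_bh")[1]
    return [
        DiffRecord(g, float(lfc[j]), float(pvals[j]), float(padj[j]))
        for j, g in enumerate(shared)
    ]


def gene_level_accessibility(
    peak_records: list[DiffRecord], assignment: dict[str, list[str]]
) -> dict[str, DiffRecord]:
    """Collapse peak-level differential records to one record per gene: the
    assigned peak with the smallest padj wins (missing padj sorts last; ties
    broken by larger |log2fc|, then lexicographic peak id).  The winning
    record's ``feature_id`` is the best peak id."""
    by_gene: dict[str, list[DiffRecord]] = {}
    for rec in peak_records:
        for g in assignment.get(rec.feature_id, []):
            by_gene.setdefault(g, []).append(rec)

    def rank(rec: DiffRecord):
        padj = np.inf if rec.padj is None else rec.padj
        return (padj, -abs(rec.log2fc), rec.feature_id)

    return {g: min(recs, key=rank) for g, recs in by_gene.items()}


def _state(log2fc: float, padj: float | None, alpha: float, lfc: float) -> str:
    if padj is None or padj > alpha:
        return "ns"
    if log2fc >= lfc:
        return "up"
    if log2fc <= -lfc:
        return "down"
    return "ns"


def classify_concordance(
    rna: list[DiffRecord],
    atac_by_gene: dict[str, DiffRecord],
    thresholds: ConcordanceThresholds | None = None,
) -> list[ConcordanceRecord]:
    """Label each RNA-tested gene by the joint (RNA, ATAC) state.

    Genes without an assigned peak record have ATAC state ``ns``.  The label
    is a pure function of the two states (concordant_up/down, discordant,
    expression_only, accessibility_only, neither); together the labels
    partition the RNA gene list.
    """
    t = thresholds or ConcordanceThresholds()
    seen: set[str] = set()
    out: list[ConcordanceRecord] = []
    for rec in rna:
        if rec.feature_id in seen:
            raise GremnetError(f"duplicate gene in RNA table: {rec.feature_id!r}")
        seen.add(rec.feature_id)
        rna_state = _state(rec.log2fc, rec.padj, t.rna_alpha, t.rna_lfc)
        arec = atac_by_gene.get(rec.feature_id)
        if arec is None:
            atac_state, best_peak = "ns", None
        else:
            atac_state = _state(arec.log2fc, arec.padj, t.atac_alpha, t.atac_lfc)
            best_peak = arec.feature_id
        out.append(
            ConcordanceRecord(
                gene_id=rec.feature_id,
                rna_state=rna_state,
                atac_state=atac_state,
                label=_LABELS[(rna_state, atac_state)],
                best_peak_id=best_peak,
            )
        )
    return out


def zscore_matrix(x: ExpressionMatrix) -> tuple[np.ndarray, list[str]]:
    """Per-gene z-scores across samples (sd with n-1 denominator).

    Returns the samples x genes z-matrix and the list of zero-variance genes,
    whose columns are all zero.
    """
    if x.n_samples < 2:
        raise ValidationError("z-scoring needs >= 2 samples")
    mean = x.values.mean(axis=0, keepdims=True)
    sd = x.values.std(axis=0, ddof=1, keepdims=True)
    flagged = [g for j, g in enumerate(x.gene_ids) if sd[0, j] == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (x.values - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return z, flagged
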