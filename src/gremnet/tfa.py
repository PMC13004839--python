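"""Transcription-factor activity estimation.

Expression is modeled as ``X = A @ P`` (samples x genes = samples x TFs times
TFs x genes); the activity matrix is the least-squares solution
``A = X @ pinv(P)`` with the Moore-Penrose pseudoinverse computed by SVD.
Binary priors are frequently rank-deficient, so small singular values
(below ``rtol * sigma_max``) are treated as zero rather than inverted.

TFs whose prior row is empty carry no constraint on the inversion; following
the usual convention of activity-inference frameworks, such a TF's activity
is its own (centered) expression when the TF is measured, and the TF is
dropped with a warning otherwise.
"""

from __future__ import annotations

import warnings

import numpy as np

from .sc_preprocess import normalize_log1p
from .types import ActivityMatrix, ExpressionMatrix, PriorMatrix, ValidationError


def estimate_tfa(
    x: ExpressionMatrix,
    prior: PriorMatrix,
    center: bool = True,
    rtol: float = 1e-10,
) -> ActivityMatrix:
    """Invert the linear system ``X = A @ P`` for the activity matrix A.

    Genes are restricted to the intersection of ``x`` and ``prior`` (>= 2
    required); with ``center=True`` (default) each gene is centered across
    samples before inversion, which removes the intercept burden from a
    model without an intercept term.  Counts input is log1p-normalized
    automatically with a warning.
    """
    if x.layer == "counts":
        warnings.warn(
            "estimate_tfa received raw counts; applying log1p normalization "
            "(target sum 10000)",
            stacklevel=2,
        )
        x = normalize_log1p(x)

    gene_pos = {g: j for j, g in enumerate(x.gene_ids)}
    shared = [g for g in prior.gene_ids if g in gene_pos]
    if len(shared) < 2:
        raise ValidationError(
            f"expression and prior share {len(shared)} gene(s); need >= 2"
        )
    prior_cols = [prior.gene_ids.index(g) for g in shared]
    x_cols = [gene_pos[g] for g in shared]

    p_mat = prior.values[:, prior_cols]
    x_mat = x.values[:, x_cols].astype(float)
    if center:
        x_mat = x_mat - x_mat.mean(axis=0, keepdims=True)

    row_nonzero = np.any(p_mat != 0, axis=1)
    if not row_nonzero.any():
        raise ValidationError("prior has no nonzero rows on the shared genes")

    a_inv = x_mat @ np.linalg.pinv(p_mat[row_nonzero], rcond=rtol)

    values_cols: list[np.ndarray] = []
    tf_ids: list[str] = []
    tags: list[str] = []
    inv_iter = iter(a_inv.T)
    for i, tf in enumerate(prior.tf_ids):
        if row_nonzero[i]:
            values_cols.append(next(inv_iter))
            tf_ids.append(tf)
            tags.append("inverted")
        elif tf in gene_pos:
            col = x.values[:, gene_pos[tf]].astype(float)
            if center:
                col = col - col.mean()
            values_cols.append(col)
            tf_ids.append(tf)
            tags.append("self_expression")
        else:
            warnings.warn(
                f"TF {tf!r} has an empty prior row and is not measured; dropped",
                stacklevel=2,
            )
    values = np.column_stack(values_cols)
    return ActivityMatrix(values, list(x.sample_ids), tf_ids, tags)
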