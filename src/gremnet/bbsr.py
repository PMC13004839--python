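"""Per-gene best-subset regression for network inference.

For each gene, a capped set of candidate TFs is preselected (prior-supported
TFs first, then by absolute correlation with the gene's expression), every
subset up to ``max_subset_size`` is scored by BIC on a centered OLS fit, and
the reported weights are BIC-weighted model averages.  Edge confidence is
the relative drop in residual sum of squares when a TF is removed from the
best model.

Scoring notes.  BIC = n*ln(rss/n) + k*ln(n) with k the subset size.  The RSS
entering the logarithm is floored at ``tss * 1e-12`` (tss = centered total
sum of squares of the gene): an exact fit would otherwise produce -inf, and residuals computed from
the Gram system carry cancellation noise of order tss * 1e-13, so the floor
must sit above it for model comparison to be deterministic.
Collinear subsets fall back to a ridge solve (lambda = 1e-8) and are
flagged in the diagnostics.  All tie-breaks (smaller subset first, then
lexicographic TF ids) are fixed so results are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import numpy as np

from .types import (
    ActivityMatrix,
    ExpressionMatrix,
    NetworkMatrix,
    PriorMatrix,
    ValidationError,
)

RSS_FLOOR_REL = 1e-12
RIDGE_LAMBDA = 1e-8


@dataclass
class BBSRConfig:
    n_preselect: int = 10
    max_subset_size: Optional[int] = None  # None: equal to n_preselect
    prior_inclusion_bonus: float = 0.0
    ic: str = "bic"

    def __post_init__(self) -> None:
        if self.max_subset_size is None:
            self.max_subset_size = self.n_preselect
        if not (1 <= self.max_subset_size <= self.n_preselect <= 20):
            raise ValidationError(
                "require 1 <= max_subset_size <= n_preselect <= 20"
            )
        if self.prior_inclusion_bonus < 0:
            raise ValidationError("prior_inclusion_bonus must be >= 0")
        if self.ic != "bic":
            raise ValidationError(f"unsupported information criterion {self.ic!r}")


@dataclass
class GeneResult:
    """Per-gene inference output and diagnostics."""

    gene_id: str
    candidates: list[str]
    best_subset: tuple[str, ...]
    best_bic: float
    weights: dict[str, float]  # model-averaged, keyed by tf id
    confidence: dict[str, float]
    ridge_flagged: bool = False


def preselect_predictors(
    y: np.ndarray,
    a: ActivityMatrix,
    prior_tfs: set[str],
    cfg: BBSRConfig,
    exclude_tf: Optional[str] = None,
) -> list[str]:
    """Rank candidate TFs: prior-supported first by |Pearson r| with y
    (descending), then the rest by |r|; ties lexicographic; up to
    ``n_preselect`` returned.  A TF equal to ``exclude_tf`` (self edge) is
    skipped; zero-variance y yields an empty list with a warning.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != a.values.shape[0]:
        raise ValidationError("y length does not match activity samples")
    yc = y - y.mean()
    sy = np.sqrt((yc**2).sum())
    if sy == 0:
        warnings.warn("zero-variance response; no predictors selected", stacklevel=2)
        return []
    z = a.values - a.values.mean(axis=0, keepdims=True)
    sz = np.sqrt((z**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(sz > 0, (z.T @ yc) / np.where(sz > 0, sz * sy, 1.0), 0.0)
    scored = [
        (tf, abs(float(r[i])))
        for i, tf in enumerate(a.tf_ids)
        if tf != exclude_tf
    ]
    in_prior = [t for t in scored if t[0] in prior_tfs]
    out_prior = [t for t in scored if t[0] not in prior_tfs]
    key = lambda t: (-t[1], t[0])
    ordered = [tf for tf, _ in sorted(in_prior, key=key)] + [
        tf for tf, _ in sorted(out_prior, key=key)
    ]
    return ordered[: cfg.n_preselect]


def score_subset(
    y: np.ndarray, z: np.ndarray, subset: tuple[int, ...]
) -> tuple[float, int, float, np.ndarray]:
    """BIC-score one candidate subset by centered OLS.

    Returns (rss, k, bic, betas).  The empty subset scores the null model
    (rss = centered total sum of squares, k = 0).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    k = len(subset)
    if n <= k + 1:
        raise ValidationError(f"need n > |subset| + 1 (n={n}, |subset|={k})")
    yc = y - y.mean()
    tss = float(yc @ yc)
    if k == 0:
        rss = tss
        betas = np.zeros(0)
    else:
        zc = z[:, list(subset)] - z[:, list(subset)].mean(axis=0, keepdims=True)
        g = zc.T @ zc
        c = zc.T @ yc
        try:
            betas = np.linalg.solve(g, c)
            if not np.all(np.isfinite(betas)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            betas = np.linalg.solve(g + RIDGE_LAMBDA * np.eye(k), c)
        rss = max(float(yc @ yc - c @ betas), 0.0)
    bic = _bic(n, rss, k, tss)
    return rss, k, bic, betas


def _bic(n: int, rss: float, k: int, tss: float) -> float:
    floor = max(tss * RSS_FLOOR_REL, 1e-300)
    return n * float(np.log(max(rss, floor) / n)) + k * float(np.log(n))


_COMB_CACHE: dict[tuple[int, int], list[np.ndarray]] = {}


def _subset_index(m: int, max_k: int) -> list[np.ndarray]:
    """Per size k, the (n_subsets_k, k) array of candidate indices."""
    key = (m, max_k)
    if key not in _COMB_CACHE:
        _COMB_CACHE[key] = [np.zeros((1, 0), dtype=np.intp)] + [
            np.array(list(combinations(range(m), k)), dtype=np.intp)
            for k in range(1, max_k + 1)
        ]
    return _COMB_CACHE[key]


def bbsr_gene(
    y: np.ndarray,
    a: ActivityMatrix,
    prior_tfs: set[str],
    cfg: Optional[BBSRConfig] = None,
    gene_id: str = "",
) -> GeneResult:
    """Enumerate subsets of the preselected TFs, pick the BIC-best model,
    and model-average coefficients with weights ~ exp(-(bic - bic_min)/2).

    With ``prior_inclusion_bonus > 0`` each subset's effective BIC is reduced
    by bonus * (number of prior-supported TFs in the subset), biasing both
    model choice and averaging toward the prior.  Confidence of TF t in the
    best model is ``max(0, 1 - rss_best / rss_best_without_t)``; TFs outside
    the best model get confidence 0.

    Subsets are solved in batches (one stacked solve per size) from the
    cached Gram matrix; the result is identical to per-subset OLS.
    """
    cfg = cfg or BBSRConfig()
    candidates = preselect_predictors(y, a, prior_tfs, cfg, exclude_tf=gene_id or None)
    if not candidates:
        return GeneResult(gene_id, [], (), float("nan"), {}, {})

    y = np.asarray(y, dtype=float)
    n = len(y)
    yc = y - y.mean()
    tss = float(yc @ yc)
    floor = max(tss * RSS_FLOOR_REL, 1e-300)
    tf_pos = {tf: i for i, tf in enumerate(a.tf_ids)}
    z = a.values[:, [tf_pos[tf] for tf in candidates]]
    zc = z - z.mean(axis=0, keepdims=True)
    gram = zc.T @ zc
    cvec = zc.T @ yc

    m = len(candidates)
    max_k = min(cfg.max_subset_size, m, n - 2)
    prior_flag = np.array([tf in prior_tfs for tf in candidates])
    by_size = _subset_index(m, max_k)

    rss_parts: list[np.ndarray] = []
    size_parts: list[np.ndarray] = []
    nprior_parts: list[np.ndarray] = []
    beta_parts: list[np.ndarray] = []  # per size: (C_k, k)
    ridge_flag = False
    for k, idx in enumerate(by_size):
        nc = idx.shape[0]
        if k == 0:
            rss_parts.append(np.array([tss]))
            size_parts.append(np.zeros(1, dtype=int))
            nprior_parts.append(np.zeros(1, dtype=int))
            beta_parts.append(np.zeros((1, 0)))
            continue
        g_stack = gram[idx[:, :, None], idx[:, None, :]]
        c_stack = cvec[idx]
        try:
            betas = np.linalg.solve(g_stack, c_stack[:, :, None])[:, :, 0]
            bad = ~np.all(np.isfinite(betas), axis=1)
        except np.linalg.LinAlgError:
            betas = np.full((nc, k), np.nan)
            bad = np.ones(nc, dtype=bool)
        if bad.any():
            ridge_flag = True
            eye = RIDGE_LAMBDA * np.eye(k)
            for si in np.nonzero(bad)[0]:
                try:
                    betas[si] = np.linalg.solve(g_stack[si], c_stack[si])
                    if not np.all(np.isfinite(betas[si])):
                        raise np.linalg.LinAlgError
                except np.linalg.LinAlgError:
                    betas[si] = np.linalg.solve(g_stack[si] + eye, c_stack[si])
        rss = np.maximum(tss - np.einsum("ck,ck->c", c_stack, betas), 0.0)
        rss_parts.append(rss)
        size_parts.append(np.full(nc, k, dtype=int))
        nprior_parts.append(prior_flag[idx].sum(axis=1) if prior_flag.any() else np.zeros(nc, dtype=int))
        beta_parts.append(betas)

    rss_all = np.concatenate(rss_parts)
    size_all = np.concatenate(size_parts)
    nprior_all = np.concatenate(nprior_parts)
    bic_all = n * np.log(np.maximum(rss_all, floor) / n) + size_all * np.log(n)
    eff_all = bic_all - cfg.prior_inclusion_bonus * nprior_all

    # offsets of each size block in the concatenated arrays
    offsets = np.cumsum([0] + [p.shape[0] for p in rss_parts])

    def subset_of(si: int) -> tuple[int, ...]:
        k = int(size_all[si])
        return tuple(by_size[k][si - offsets[k]])

    def tie_key(si: int):
        sub = subset_of(si)
        return (int(size_all[si]), tuple(sorted(candidates[i] for i in sub)))

    def argbest(mask: Optional[np.ndarray] = None) -> int:
        eff = eff_all if mask is None else np.where(mask, eff_all, np.inf)
        lo = float(eff.min())
        ties = np.nonzero(eff == lo)[0]
        if ties.size == 1:
            return int(ties[0])
        return int(min(ties, key=tie_key))

    best_si = argbest()
    best_sub = subset_of(best_si)

    # model averaging over all enumerated subsets
    w = np.exp(-0.5 * (eff_all - eff_all[best_si]))
    w /= w.sum()
    beta_bar = np.zeros(m)
    for k, idx in enumerate(by_size):
        if k == 0:
            continue
        wk = w[offsets[k] : offsets[k + 1]]
        np.add.at(beta_bar, idx.ravel(), (wk[:, None] * beta_parts[k]).ravel())

    # confidence: rss drop when each best-model TF is removed
    contains = np.zeros((m, len(rss_all)), dtype=bool)
    for k, idx in enumerate(by_size):
        if k == 0:
            continue
        blk = contains[:, offsets[k] : offsets[k + 1]]
        for col in range(k):
            blk[idx[:, col], np.arange(idx.shape[0])] = True
    confidence: dict[str, float] = {}
    rss_best = max(float(rss_all[best_si]), floor)
    for i in best_sub:
        si_wo = argbest(~contains[i])
        rss_wo = max(float(rss_all[si_wo]), floor)
        confidence[candidates[i]] = max(0.0, 1.0 - rss_best / rss_wo)

    weights = {tf: float(beta_bar[i]) for i, tf in enumerate(candidates)}
    return GeneResult(
        gene_id=gene_id,
        candidates=candidates,
        best_subset=tuple(candidates[i] for i in best_sub),
        best_bic=float(bic_all[best_si]),
        weights=weights,
        confidence=confidence,
        ridge_flagged=ridge_flag,
    )


def infer_network(
    x: ExpressionMatrix,
    a: ActivityMatrix,
    prior: Optional[PriorMatrix] = None,
    cfg: Optional[BBSRConfig] = None,
) -> tuple[NetworkMatrix, list[GeneResult]]:
    """Run the per-gene subset regression over every gene of ``x``.

    Samples are inner-joined between expression and activities (>= 3
    required); genes are treated independently, so permuting gene order only
    permutes output columns.
    """
    cfg = cfg or BBSRConfig()
    sample_pos = {s: i for i, s in enumerate(a.sample_ids)}
    shared = [s for s in x.sample_ids if s in sample_pos]
    if len(shared) < 3:
        raise ValidationError(f"{len(shared)} shared sample(s); need >= 3")
    xv = x.values[[x.sample_ids.index(s) for s in shared], :]
    av = a.values[[sample_pos[s] for s in shared], :]
    a_shared = ActivityMatrix(av, shared, list(a.tf_ids))

    prior_sets: dict[str, set[str]] = {}
    in_prior = np.zeros((len(a.tf_ids), x.n_genes), dtype=bool)
    if prior is not None:
        pg = {g: j for j, g in enumerate(prior.gene_ids)}
        pt = {t: i for i, t in enumerate(prior.tf_ids)}
        for j, g in enumerate(x.gene_ids):
            if g in pg:
                col = prior.values[:, pg[g]]
                s = {prior.tf_ids[i] for i in np.nonzero(col)[0]}
                prior_sets[g] = s
                for t in s:
                    if t in pt and t in a.tf_ids:
                        in_prior[a.tf_ids.index(t), j] = True

    tf_index = {tf: i for i, tf in enumerate(a.tf_ids)}
    weights = np.zeros((len(a.tf_ids), x.n_genes))
    confidence = np.zeros((len(a.tf_ids), x.n_genes))
    results: list[GeneResult] = []
    for j, g in enumerate(x.gene_ids):
        res = bbsr_gene(xv[:, j], a_shared, prior_sets.get(g, set()), cfg, gene_id=g)
        results.append(res)
        for tf, wgt in res.weights.items():
            weights[tf_index[tf], j] = wgt
        for tf, conf in res.confidence.items():
            confidence[tf_index[tf], j] = conf
    net = NetworkMatrix(weights, confidence, list(a.tf_ids), list(x.gene_ids), in_prior)
    return net, results


def summarize_tf_degrees(
    net: NetworkMatrix, min_conf: float = 0.0, min_targets: int = 4
):
    """Count, per TF, targets regulated with confidence >= ``min_conf`` (only
    edges with positive confidence count as regulated); return TFs with at
    least ``min_targets`` such targets, ranked highest to lowest, ties
    lexicographic.
    """
    import pandas as pd

    if not (0 <= min_conf <= 1):
        raise ValidationError("min_conf must lie in [0, 1]")
    regulated = (net.confidence > 0) & (net.confidence >= min_conf)
    counts = regulated.sum(axis=1)
    rows = [
        (tf, int(c)) for tf, c in zip(net.tf_ids, counts) if c >= min_targets
    ]
    rows.sort(key=lambda t: (-t[1], t[0]))
    return pd.DataFrame(rows, columns=["tf", "n_targets"])
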