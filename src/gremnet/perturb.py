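"""In-silico perturbation: predict condition expression from condition TFA
and the wild-type network, and score agreement with observations by R².

R² here is 1 - SS_res / SS_tot with SS_res the plain squared difference
between observed and predicted entries and SS_tot the squared deviation of
the observations from their per-gene means.  It equals 1 for a perfect
prediction, 0 for the per-gene-mean predictor, can be negative for anything
worse, and is invariant to adding a common constant to both matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import ActivityMatrix, ExpressionMatrix, NetworkMatrix, ValidationError


@dataclass
class SimulationResult:
    x_hat: ExpressionMatrix
    r2_global: float
    r2_per_gene: dict[str, float]
    n_genes_used: int
    n_samples_used: int
    quantiles: dict[str, float] = field(default_factory=dict)
    n_zero_variance_genes: int = 0


def simulate_expression(
    a_cond: ActivityMatrix, net: NetworkMatrix, conf_threshold: float = 0.0
) -> ExpressionMatrix:
    """Predict expression as ``A_cond @ W`` over the shared TFs, after zeroing
    network weights whose confidence is below ``conf_threshold``."""
    if not (0.0 <= conf_threshold <= 1.0):
        raise ValidationError("conf_threshold must lie in [0, 1]")
    tf_pos = {t: i for i, t in enumerate(net.tf_ids)}
    shared = [t for t in a_cond.tf_ids if t in tf_pos]
    if not shared:
        raise ValidationError("activity and network share no TFs")
    a_idx = [a_cond.tf_ids.index(t) for t in shared]
    w_idx = [tf_pos[t] for t in shared]
    w = net.weights[w_idx, :].copy()
    w[net.confidence[w_idx, :] < conf_threshold] = 0.0
    x_hat = a_cond.values[:, a_idx] @ w
    return ExpressionMatrix(
        x_hat, list(a_cond.sample_ids), list(net.gene_ids), layer="lognorm"
    )


def r_squared(
    x_obs: ExpressionMatrix, x_hat: ExpressionMatrix, mode: str = "global"
):
    """Coefficient of determination between observed and predicted expression.

    Samples and genes are inner-joined; genes with zero observed variance are
    excluded (their count is reported by :func:`evaluate_perturbation`).
    ``mode='global'`` pools all matched entries; ``mode='per_gene'`` returns a
    per-gene map.
    """
    if mode not in ("global", "per_gene"):
        raise ValueError(f"unknown mode {mode!r}")
    obs, hat, genes = _align(x_obs, x_hat)
    var = obs.var(axis=0)
    usable = var > 0
    if not usable.any():
        raise ValidationError("all matched genes have zero observed variance")
    obs_u, hat_u = obs[:, usable], hat[:, usable]
    ss_res = (obs_u - hat_u) ** 2
    ss_tot = (obs_u - obs_u.mean(axis=0, keepdims=True)) ** 2
    if mode == "global":
        return 1.0 - float(ss_res.sum()) / float(ss_tot.sum())
    genes_u = [g for g, u in zip(genes, usable) if u]
    return {
        g: 1.0 - float(ss_res[:, j].sum()) / float(ss_tot[:, j].sum())
        for j, g in enumerate(genes_u)
    }


def _align(x_obs: ExpressionMatrix, x_hat: ExpressionMatrix):
    hs = {s: i for i, s in enumerate(x_hat.sample_ids)}
    hg = {g: j for j, g in enumerate(x_hat.gene_ids)}
    samples = [s for s in x_obs.sample_ids if s in hs]
    genes = [g for g in x_obs.gene_ids if g in hg]
    if not samples or not genes:
        raise ValidationError("observed and predicted matrices do not overlap")
    oi = [x_obs.sample_ids.index(s) for s in samples]
    oj = [x_obs.gene_ids.index(g) for g in genes]
    obs = x_obs.values[np.ix_(oi, oj)]
    hat = x_hat.values[np.ix_([hs[s] for s in samples], [hg[g] for g in genes])]
    return obs, hat, genes


def evaluate_perturbation(
    x_obs: ExpressionMatrix,
    a_cond: ActivityMatrix,
    net: NetworkMatrix,
    conf_threshold: float = 0.0,
    center_obs: bool = False,
) -> SimulationResult:
    """Chain :func:`simulate_expression` and :func:`r_squared` and report the
    global R², the per-gene R² distribution, and the gene/sample counts used.

    ``center_obs`` subtracts each observed gene's mean before scoring; use it
    when the prediction lives on the centered scale (TFA estimated from
    centered expression).
    """
    x_hat = simulate_expression(a_cond, net, conf_threshold)
    if center_obs:
        x_obs = ExpressionMatrix(
            x_obs.values - x_obs.values.mean(axis=0, keepdims=True),
            list(x_obs.sample_ids),
            list(x_obs.gene_ids),
            layer="lognorm",
        )
    obs, hat, genes = _align(x_obs, x_hat)
    n_zero = int((obs.var(axis=0) == 0).sum())
    r2g = r_squared(x_obs, x_hat, mode="global")
    per_gene = r_squared(x_obs, x_hat, mode="per_gene")
    vals = np.array(sorted(per_gene.values()))
    quantiles = {
        q: float(np.quantile(vals, float(q))) for q in ("0.1", "0.25", "0.5", "0.75", "0.9")
    }
    return SimulationResult(
        x_hat=x_hat,
        r2_global=r2g,
        r2_per_gene=per_gene,
        n_genes_used=len(per_gene),
        n_samples_used=obs.shape[0],
        quantiles=quantiles,
        n_zero_variance_genes=n_zero,
    )
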