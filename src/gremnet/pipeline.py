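"""End-to-end orchestration: simulate -> prior -> TFA -> network -> KO score.

Also writes the full synthetic fixture set as standard flat files so every
CLI stage can be run file-in / file-out.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
from sklearn.metrics import average_precision_score

from . import io_formats as io
from .bbsr import BBSRConfig, infer_network
from .perturb import SimulationResult, evaluate_perturbation
from .prior import assign_peaks_to_genes, build_prior, hits_from_scaffold
from .synthetic import SimParams, TruthBundle, generate_expression, generate_scaffold, generate_truth
from .tfa import estimate_tfa
from .types import ExpressionMatrix, NetworkMatrix, PriorMatrix


def scaffold_prior(bundle: TruthBundle, window_bp: Optional[int] = None) -> PriorMatrix:
    """Build the motif/accessibility prior from the bundle's genome scaffold
    (generating the scaffold at ``window_bp`` if absent)."""
    scaffold = bundle.scaffold
    if scaffold is None or (window_bp is not None and scaffold.window_bp != window_bp):
        scaffold = generate_scaffold(bundle, window_bp=window_bp or 50_000)
        bundle.scaffold = scaffold
    assignment = assign_peaks_to_genes(
        scaffold.peaks, scaffold.genes, scaffold.window_bp
    )
    return build_prior(
        scaffold.peaks,
        hits_from_scaffold(scaffold),
        assignment,
        scaffold.motif_to_tf,
        tf_ids=bundle.tf_ids,
        gene_ids=bundle.gene_ids,
    )


def edge_recovery_aupr(net: NetworkMatrix, truth: NetworkMatrix) -> float:
    """Area under precision-recall for confidence-ranked edges against the
    true support (TF/gene sets aligned by id)."""
    ti = [truth.tf_ids.index(t) for t in net.tf_ids]
    gi = [truth.gene_ids.index(g) for g in net.gene_ids]
    y_true = (truth.weights[np.ix_(ti, gi)] != 0).ravel().astype(int)
    scores = net.confidence.ravel()
    return float(average_precision_score(y_true, scores))


def run_pipeline(
    params: Optional[SimParams] = None,
    seed: int = 0,
    window_bp: int = 50_000,
    cfg: Optional[BBSRConfig] = None,
    conf_threshold: float = 0.0,
) -> dict:
    """Full synthetic study: generate truth, build the (corrupted) motif
    prior from the scaffold, estimate WT TFA, infer the network, estimate KO
    TFA, simulate KO expression through the WT network, and score recovery.

    Returns a dict with the bundle, the prior, the inferred network, the
    edge-recovery AUPR, and the KO-simulation result.
    """
    bundle = generate_truth(params, seed=seed)
    prior = scaffold_prior(bundle, window_bp)
    x_wt = generate_expression(bundle, "wt")
    x_ko = generate_expression(bundle, "ko")

    a_wt = estimate_tfa(x_wt, prior, center=True)
    net, diagnostics = infer_network(x_wt, a_wt, prior, cfg)
    aupr = edge_recovery_aupr(net, bundle.w_true)

    a_ko = estimate_tfa(x_ko, prior, center=True)
    sim = evaluate_perturbation(
        x_ko, a_ko, net, conf_threshold=conf_threshold, center_obs=True
    )
    return {
        "bundle": bundle,
        "prior": prior,
        "x_wt": x_wt,
        "x_ko": x_ko,
        "a_wt": a_wt,
        "a_ko": a_ko,
        "network": net,
        "diagnostics": diagnostics,
        "aupr": aupr,
        "ko_simulation": sim,
    }


def write_simulation(bundle: TruthBundle, outdir, window_bp: int = 50_000) -> dict:
    """Write the bundle as a flat-file fixture set and return the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scaffold = bundle.scaffold
    if scaffold is None:
        scaffold = generate_scaffold(bundle, window_bp=window_bp)
        bundle.scaffold = scaffold

    paths = {k: outdir / v for k, v in {
        "expr_wt": "expr_wt.tsv",
        "expr_ko": "expr_ko.tsv",
        "tss": "tss.tsv",
        "peaks": "peaks.bed",
        "motifs": "motifs.meme",
        "hits": "hits.tsv",
        "motif_map": "motif_map.tsv",
        "prior_true": "prior_true.tsv",
        "network_true": "network_true.tsv",
        "a_wt": "a_wt.tsv",
        "a_ko": "a_ko.tsv",
        "perturbed": "perturbed_tfs.txt",
    }.items()}

    x_wt = generate_expression(bundle, "wt")
    x_ko = generate_expression(bundle, "ko")
    if x_wt.layer == "counts":
        io.write_counts(x_wt, paths["expr_wt"])
        io.write_counts(x_ko, paths["expr_ko"])
    else:
        _write_dense(x_wt, paths["expr_wt"])
        _write_dense(x_ko, paths["expr_ko"])

    io.write_tss_table(scaffold.genes, paths["tss"])
    io.write_bed_peaks(scaffold.peaks, paths["peaks"])
    io.write_meme_motifs(scaffold.pwms, paths["motifs"])

    import pandas as pd

    L = {m.motif_id: len(m) for m in scaffold.pwms}
    hits_df = pd.DataFrame(
        [
            (mid, pid, off, off + L[mid], strand, 0.0)
            for (mid, pid, off, strand) in scaffold.motif_hits
        ],
        columns=["motif_id", "sequence_name", "start", "stop", "strand", "score"],
    )
    io.write_hits_table(hits_df, paths["hits"])
    with open(paths["motif_map"], "w") as fh:
        fh.write("motif_id\ttf\n")
        for mid in sorted(scaffold.motif_to_tf):
            fh.write(f"{mid}\t{scaffold.motif_to_tf[mid]}\n")

    io.write_prior(bundle.prior_true, paths["prior_true"])
    io.write_network(bundle.w_true, paths["network_true"])
    io.write_activities(bundle.a_wt, paths["a_wt"])
    io.write_activities(bundle.a_ko, paths["a_ko"])
    with open(paths["perturbed"], "w") as fh:
        for tf in sorted(bundle.perturbed_tfs):
            fh.write(tf + "\n")
    return paths


def _write_dense(x: ExpressionMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join([""] + x.gene_ids) + "\n")
        for i, sid in enumerate(x.sample_ids):
            fh.write("\t".join([sid] + [io._fmt(v) for v in x.values[i]]) + "\n")
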