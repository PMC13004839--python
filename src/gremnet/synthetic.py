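"""Ground-truth regulatory systems with matched genome scaffolds.

The generator realizes the generative model the inference stack assumes:
expression is the product of a per-sample TF-activity matrix and a sparse
signed TF-by-gene weight matrix, plus Gaussian noise (optionally pushed
through a count link).  Knockout conditions zero the activity columns of the
perturbed TFs.  A synthetic chromosome carries one TSS per gene and, for each
prior-supported edge, an accessible peak near the target TSS containing a
motif occurrence of the regulating TF, so that the motif-prior builder can be
validated against the known truth.

All randomness flows from a single integer seed through named substreams, so
identical seeds give bit-identical bundles on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .types import (
    ActivityMatrix,
    ExpressionMatrix,
    GeneAnnotation,
    GremnetError,
    NetworkMatrix,
    Peak,
    PriorMatrix,
    PWM,
    ValidationError,
)

_SUBSTREAM = {"truth": 0, "wt": 1, "ko": 2, "scaffold": 3, "corrupt": 4}


def _rng(seed: int, stream: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_SUBSTREAM[stream], extra))
    )


@dataclass
class SimParams:
    """Knobs of the generative model.

    Defaults describe a mid-sized fibroblast-like system: 20 TFs regulating
    400 genes with 3 regulators per gene, 300 cells per condition, Gaussian
    activities, residual noise sd 0.25 on the log scale, and a prior that
    misses 20% of true edges and adds false edges at a 2% rate.
    """

    n_tf: int = 20
    n_gene: int = 400
    n_sample_wt: int = 300
    n_sample_ko: int = 300
    edges_per_gene: int = 3
    weight_scale: float = 1.0
    # tf_signed: each TF is consistently an activator or a repressor (sign
    # drawn per TF); edge_signed: sign drawn independently per edge;
    # unit: all weights exactly +1.  Activities are only identifiable from an
    # unsigned prior under tf_signed (or unit), hence the default.
    weight_mode: str = "tf_signed"
    activity_model: str = "gaussian"  # gaussian | lognormal
    noise_sd: float = 0.25
    count_model: str = "none"  # none | poisson | negbin
    nb_dispersion: float = 10.0
    prior_fpr: float = 0.02
    prior_fnr: float = 0.2
    n_perturb: int = 1
    motif_length: int = 8
    peak_width: int = 400
    gene_spacing_bp: Optional[int] = None  # None: derived from the window

    def __post_init__(self) -> None:
        if self.n_tf < 2:
            raise ValidationError("n_tf must be >= 2")
        if not (1 <= self.edges_per_gene <= self.n_tf):
            raise ValidationError("require 1 <= edges_per_gene <= n_tf")
        if self.weight_mode not in ("tf_signed", "edge_signed", "unit"):
            raise ValidationError(f"unknown weight_mode {self.weight_mode!r}")
        if self.activity_model not in ("gaussian", "lognormal"):
            raise ValidationError(f"unknown activity_model {self.activity_model!r}")
        if self.count_model not in ("none", "poisson", "negbin"):
            raise ValidationError(f"unknown count_model {self.count_model!r}")
        if self.noise_sd < 0 or self.weight_scale <= 0 or self.nb_dispersion <= 0:
            raise ValidationError("scale parameters must be positive")
        if not (0 <= self.prior_fpr < 1 and 0 <= self.prior_fnr < 1):
            raise ValidationError("prior_fpr and prior_fnr must lie in [0, 1)")
        if not (1 <= self.n_perturb <= self.n_tf):
            raise ValidationError("require 1 <= n_perturb <= n_tf")


@dataclass
class GenomeScaffold:
    """Synthetic chromosome layout tying the network truth to genomic features."""

    chrom_lengths: dict[str, int]
    genes: list[GeneAnnotation]
    peaks: list[Peak]
    motif_hits: list[tuple[str, str, int, str]]  # (motif_id, peak_id, offset, strand)
    pwms: list[PWM]
    motif_to_tf: dict[str, str]
    window_bp: int
    sequences: Optional[dict[str, str]] = None


@dataclass
class TruthBundle:
    """Everything needed to score recovery of the generative system."""

    w_true: NetworkMatrix
    a_wt: ActivityMatrix
    a_ko: ActivityMatrix
    prior_true: PriorMatrix
    perturbed_tfs: set[str]
    scaffold: Optional[GenomeScaffold]
    params: SimParams
    seed: int

    @property
    def tf_ids(self) -> list[str]:
        return self.w_true.tf_ids

    @property
    def gene_ids(self) -> list[str]:
        return self.w_true.gene_ids


def generate_truth(
    params: SimParams | None = None,
    seed: int = 0,
    with_scaffold: bool = False,
    window_bp: int = 50_000,
) -> TruthBundle:
    """Draw a ground-truth system: sparse signed weights, WT/KO activities,
    the uncorrupted prior (the exact support of the weights), and the set of
    knocked-out TFs.

    Each gene receives exactly ``edges_per_gene`` regulators.  The weight
    support is redrawn (bounded retries) until its rows are linearly
    independent, so the TFA inversion is identifiable.
    """
    p = params or SimParams()
    tf_ids = [f"TF{i:03d}" for i in range(p.n_tf)]
    gene_ids = [f"G{i:04d}" for i in range(p.n_gene)]

    rng = _rng(seed, "truth")
    w = None
    for attempt in range(20):
        cand = np.zeros((p.n_tf, p.n_gene))
        tf_signs = rng.choice([-1.0, 1.0], size=p.n_tf)
        for j in range(p.n_gene):
            regs = rng.choice(p.n_tf, size=p.edges_per_gene, replace=False)
            if p.weight_mode == "unit":
                cand[regs, j] = 1.0
            else:
                if p.weight_mode == "tf_signed":
                    signs = tf_signs[regs]
                else:
                    signs = rng.choice([-1.0, 1.0], size=p.edges_per_gene)
                mags = p.weight_scale * rng.uniform(0.5, 1.5, size=p.edges_per_gene)
                cand[regs, j] = signs * mags
        support = (cand != 0).astype(float)
        if np.linalg.matrix_rank(support) == p.n_tf:
            w = cand
            break
    if w is None:
        raise GremnetError(
            "could not draw a prior with linearly independent rows; "
            "increase n_gene or edges_per_gene"
        )
    support = (w != 0).astype(float)

    perturbed_idx = sorted(rng.choice(p.n_tf, size=p.n_perturb, replace=False).tolist())
    perturbed = {tf_ids[i] for i in perturbed_idx}

    a_wt = _draw_activities(p, p.n_sample_wt, "WT", _rng(seed, "wt"))
    a_ko_vals = _draw_activities(p, p.n_sample_ko, "KO", _rng(seed, "ko"))
    a_ko_vals.values[:, perturbed_idx] = 0.0

    a_wt.tf_ids = list(tf_ids)
    a_ko_vals.tf_ids = list(tf_ids)

    w_true = NetworkMatrix(w, support.copy(), tf_ids, gene_ids, in_prior=support > 0)
    prior_true = PriorMatrix(support, list(tf_ids), list(gene_ids))

    bundle = TruthBundle(
        w_true=w_true,
        a_wt=a_wt,
        a_ko=a_ko_vals,
        prior_true=prior_true,
        perturbed_tfs=perturbed,
        scaffold=None,
        params=p,
        seed=seed,
    )
    if with_scaffold:
        bundle.scaffold = generate_scaffold(bundle, window_bp=window_bp)
    return bundle


def _draw_activities(
    p: SimParams, n: int, prefix: str, rng: np.random.Generator
) -> ActivityMatrix:
    if p.activity_model == "gaussian":
        vals = rng.normal(0.0, 1.0, size=(n, p.n_tf))
    else:
        vals = rng.lognormal(0.0, 0.5, size=(n, p.n_tf))
    sample_ids = [f"{prefix}_{i:04d}" for i in range(n)]
    tf_ids = [f"TF{i:03d}" for i in range(p.n_tf)]
    return ActivityMatrix(vals, sample_ids, tf_ids)


def generate_expression(
    bundle: TruthBundle, condition: str = "wt", seed: Optional[int] = None
) -> ExpressionMatrix:
    """Realize expression for one condition from the bundle's truth.

    The latent matrix is ``A_cond @ W_true`` plus iid Gaussian noise of sd
    ``noise_sd``.  With ``count_model='none'`` the latent matrix is returned
    on the lognorm layer.  Otherwise counts are drawn with mean
    ``10 * softplus(latent + 1)`` — a smooth positive link that behaves like
    an exponential for small values and linearly for large ones — from a
    Poisson or a gamma-Poisson (negative binomial, ``var = mu + mu^2/r``).
    """
    if condition not in ("wt", "ko"):
        raise ValueError(f"condition must be 'wt' or 'ko', got {condition!r}")
    p = bundle.params
    a = bundle.a_wt if condition == "wt" else bundle.a_ko
    rng = _rng(bundle.seed if seed is None else seed, condition, extra=97)

    latent = a.values @ bundle.w_true.weights
    if p.noise_sd > 0:
        latent = latent + rng.normal(0.0, p.noise_sd, size=latent.shape)

    if p.count_model == "none":
        return ExpressionMatrix(
            latent, list(a.sample_ids), list(bundle.gene_ids), layer="lognorm"
        )
    mu = 10.0 * np.logaddexp(0.0, latent + 1.0)  # 10 * softplus(latent + 1)
    if p.count_model == "poisson":
        counts = rng.poisson(mu)
    else:
        lam = rng.gamma(shape=p.nb_dispersion, scale=mu / p.nb_dispersion)
        counts = rng.poisson(lam)
    return ExpressionMatrix(
        counts.astype(float), list(a.sample_ids), list(bundle.gene_ids), layer="counts"
    )


def generate_scaffold(
    bundle: TruthBundle,
    window_bp: int = 50_000,
    seed: Optional[int] = None,
    fpr: Optional[float] = None,
    fnr: Optional[float] = None,
    with_sequences: bool = False,
) -> GenomeScaffold:
    """Lay out TSSs, peaks, and motif occurrences consistent with the truth.

    One TSS per gene on a single synthetic chromosome, spaced widely enough
    that a peak within ``window_bp`` of its target TSS cannot be assigned to
    any other gene.  Every surviving true edge (t, g) gets a peak whose
    midpoint lies within ``window_bp`` of g's TSS and which contains one
    occurrence of t's motif; a fraction ``fnr`` of true edges get no peak and
    decoy peak/hit pairs for absent edges appear at rate ``fpr``.
    """
    if window_bp <= 0:
        raise ValidationError("window_bp must be positive")
    p = bundle.params
    fpr = p.prior_fpr if fpr is None else fpr
    fnr = p.prior_fnr if fnr is None else fnr
    rng = _rng(bundle.seed if seed is None else seed, "scaffold")

    min_spacing = 2 * window_bp + p.peak_width + 1000
    spacing = p.gene_spacing_bp if p.gene_spacing_bp is not None else min_spacing
    if spacing < min_spacing:
        raise GremnetError(
            f"gene spacing {spacing} bp is too dense for a {window_bp} bp "
            f"window; need >= {min_spacing} bp or a larger chromosome"
        )
    margin = window_bp + p.peak_width
    chrom = "chrS"
    genes = [
        GeneAnnotation(
            g, chrom, margin + j * spacing, "+" if rng.random() < 0.5 else "-"
        )
        for j, g in enumerate(bundle.gene_ids)
    ]
    chrom_len = margin + (p.n_gene - 1) * spacing + margin

    pwms = _make_pwms(bundle.tf_ids, p.motif_length, rng)
    motif_to_tf = {m.motif_id: m.tf_name for m in pwms}
    tf_to_motif = {v: k for k, v in motif_to_tf.items()}

    peaks: list[Peak] = []
    hits: list[tuple[str, str, int, str]] = []
    sequences: dict[str, str] = {} if with_sequences else None
    hw = p.peak_width // 2
    max_jitter = window_bp - hw  # keeps the midpoint within the window

    def _add_peak(tf: str, gene_idx: int) -> None:
        tss = genes[gene_idx].tss
        mid = tss + int(rng.integers(-max_jitter, max_jitter + 1))
        start = max(0, mid - hw)
        end = start + p.peak_width
        pid = f"pk{len(peaks):06d}"
        peaks.append(Peak(pid, chrom, start, end))
        motif_id = tf_to_motif[tf]
        L = p.motif_length
        offset = int(rng.integers(0, p.peak_width - L + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        hits.append((motif_id, pid, offset, strand))
        if sequences is not None:
            seq = "".join(rng.choice(list("ACGT"), size=p.peak_width))
            pwm = pwms[bundle.tf_ids.index(tf)]
            ins = pwm.consensus
            if strand == "-":
                ins = _revcomp(ins)
            sequences[pid] = seq[:offset] + ins + seq[offset + L :]

    support = bundle.prior_true.values > 0
    for t_idx, tf in enumerate(bundle.tf_ids):
        for g_idx in range(p.n_gene):
            if support[t_idx, g_idx]:
                if rng.random() >= fnr:  # survives the false-negative draw
                    _add_peak(tf, g_idx)
            elif fpr > 0 and rng.random() < fpr:
                _add_peak(tf, g_idx)

    return GenomeScaffold(
        chrom_lengths={chrom: chrom_len},
        genes=genes,
        peaks=peaks,
        motif_hits=hits,
        pwms=pwms,
        motif_to_tf=motif_to_tf,
        window_bp=window_bp,
        sequences=sequences,
    )


def _make_pwms(tf_ids: list[str], length: int, rng: np.random.Generator) -> list[PWM]:
    """One sharply informative motif per TF (dominant base prob 0.85)."""
    pwms = []
    for tf in tf_ids:
        dominant = rng.integers(0, 4, size=length)
        probs = np.full((length, 4), 0.05)
        probs[np.arange(length), dominant] = 0.85
        pwms.append(PWM(f"M_{tf}", tf, probs))
    return pwms


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def corrupt_prior(
    prior: PriorMatrix, fpr: float, fnr: float, seed: int = 0
) -> PriorMatrix:
    """Drop each true edge with probability ``fnr`` and add each absent edge
    with probability ``fpr``; deterministic under the seed."""
    if not (0 <= fpr < 1 and 0 <= fnr < 1):
        raise ValidationError("fpr and fnr must lie in [0, 1)")
    rng = _rng(seed, "corrupt")
    present = prior.values > 0
    u = rng.random(prior.values.shape)
    keep_true = present & (u >= fnr)
    add_false = (~present) & (u < fpr)
    values = np.where(keep_true | add_false, 1.0, 0.0)
    return PriorMatrix(values, list(prior.tf_ids), list(prior.gene_ids))
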