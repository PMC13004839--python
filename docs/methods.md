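# Methods

## Model

The pipeline treats gene expression as the product of latent transcription-
factor activities and a sparse regulatory network:

    X  ≈  A · W

where `X` is samples × genes (log-scale expression), `A` is samples × TFs
(transcription-factor activity, TFA), and `W` is TFs × genes (signed
regulatory weights).  Neither `A` nor `W` is observed.  The pipeline breaks
the joint estimation into the standard two-step scheme:

1. a **prior connectivity matrix** `P` (TFs × genes, binary) is built from
   chromatin accessibility: a TF is connected to a gene when its binding
   motif occurs inside an accessible peak whose midpoint lies within a
   window of the gene's TSS;
2. **TFA estimation** solves `X = A·P` for `A` by least squares,
   `A = X·P⁺` with `P⁺` the Moore–Penrose pseudoinverse;
3. **network inference** regresses each gene's expression on the estimated
   activities with best-subset selection, yielding signed weights and
   per-edge confidences;
4. **in-silico knockout validation** multiplies knockout-condition TFA by
   the wild-type network and scores the prediction against observed
   knockout expression with R²;
5. **concordance classification** labels genes by the joint direction and
   significance of expression and accessibility changes.

## Prior construction

PWMs are scored as log2 likelihood ratios against the background,
`Σᵢ log2(pᵢ(b)/bg(b))`, with a pseudocount of 1e-3 added to the motif
probabilities and renormalized (so a uniform motif scores exactly 0
everywhere).  Both strands are scanned; each position reports the better
strand.  `N` bases contribute 0.

P-values are exact: scores are discretized to 1e-3 bins and the full
distribution of the discretized score under the background model is built by
dynamic programming over motif positions.  A hit's p-value is the tail mass
at its bin, with the bin computed by the same per-position discretization
the DP uses, so DP and brute-force enumeration agree exactly (with a uniform
background all probabilities are dyadic and float sums are exact).  The DP
is refused for motifs longer than 20 positions (table size); score
thresholds have no length limit.

Peak-to-gene assignment is strand-agnostic and inclusive: a peak is
assigned to every gene whose TSS is within `window_bp` of the peak midpoint
(`|TSS − midpoint| ≤ window_bp`, midpoint = floor((start+end)/2)).  The
default window is 50 kb, configurable; enhancer–promoter distances observed
in mammalian data motivate windows anywhere from 10 kb to 300 kb.  The prior
is binary by default because the TFA inversion is sensitive to weight scale
and no principled weighting is available from motif evidence alone; a
weighted mode (hit counts) exists.

## TFA estimation

`A = X·P⁺` with the pseudoinverse computed by SVD; singular values below
`rtol·σ_max` (rtol = 1e-10) are treated as zero — binary priors are often
rank-deficient and the behavior must be defined rather than incidental.
Genes are centered across samples before inversion by default (the model
has no intercept).  TFs with an empty prior row carry no constraint: their
activity falls back to the TF's own centered expression when the TF is
among the measured genes (tagged `self_expression`), otherwise the TF is
dropped with a warning.

## Network inference (best-subset regression)

Per gene, up to `n_preselect` (default 10) candidate TFs are kept:
prior-supported TFs first, ordered by |Pearson r| with the gene, then the
remainder by |r|; ties break lexicographically; the gene's own TF is
excluded (no self-edges).  Every subset up to `max_subset_size` (default =
`n_preselect`) is scored by OLS on centered data with

    BIC = n·ln(RSS/n) + k·ln(n).

The best model minimizes BIC (ties: smaller subset, then lexicographic TF
ids).  Reported weights are model averages, `β̄ = Σ_M w_M β_M` with
`w_M ∝ exp(−(BIC_M − BIC_min)/2)`.  Confidence of TF t in the best model is
`max(0, 1 − RSS_best / RSS_best∖t)`, where best∖t is the best enumerated
model not containing t; TFs outside the best model have confidence exactly
0, so the confidence support is the selected network.  Prior knowledge can
additionally bias selection through an optional BIC bonus per prior edge
(off by default).

This BIC-enumeration scoring is a deliberate, transparent replacement for
Zellner-g-prior Bayesian subset machinery: it is deterministic,
hyperparameter-free, and checkable against an independent exhaustive
implementation to 1e-8.

Numerical choices: subsets are solved from the gene's Gram matrix in
batches (identical to per-subset OLS); the RSS entering the logarithm is
floored at `tss·1e-12` because Gram-based residuals carry cancellation
noise of order `tss·1e-13` — without the floor, "best subset" on noiseless
data would depend on rounding noise.  Collinear subsets fall back to a
ridge solve (λ = 1e-8) and are flagged.  All tie-breaks are fixed, so runs
are bit-reproducible.

## Knockout simulation and R²

Predicted expression is `X̂ = A_KO · W_WT` over shared TFs, optionally
zeroing edges below a confidence threshold (default 0: use all inferred
edges).  R² = 1 − Σ(x−x̂)² / Σ(x−x̄_gene)², pooled over all matched entries
(global) or per gene.  It is 1 for a perfect prediction, 0 for the
per-gene-mean predictor, negative for worse, invariant to a common additive
shift, and never above 1.  Genes with zero observed variance are excluded
and counted.  When the TFA was estimated from centered expression the
prediction lives on the centered scale; `evaluate_perturbation` therefore
takes a `center_obs` flag (the pipeline sets it).

## Concordance classification

A gene is RNA-"up" when padj ≤ 0.05 and log2FC ≥ 0.25, "down" with
log2FC ≤ −0.25, else not significant; ATAC states use FDR ≤ 0.05 and
|log2FC| ≥ 0.1.  All comparisons are inclusive at the threshold.  A missing
adjusted p-value is never significant.  Multiple peaks per gene are
collapsed to the peak with the smallest padj (ties: larger |log2FC|, then
lexicographic peak id) — the best-peak rule preserves directionality, which
averaging would dilute.  The joint (RNA, ATAC) state maps to one of six
labels (concordant up/down, discordant, expression-only,
accessibility-only, neither), which partition the RNA gene list.  The
built-in differential test is a Welch t-test with Benjamini–Hochberg
step-up adjustment; it exists so synthetic end-to-end runs need no external
caller and is not a substitute for count-based differential models on real
data.  ATAC fold-change orientation must match the RNA contrast; the
caller is responsible for the sign convention of the input tables.

## Synthetic data generator

The generator realizes the model literally: `W` has exactly
`edges_per_gene` regulators per gene with magnitudes
`weight_scale·U(0.5, 1.5)`; activities are iid standard Gaussian (or
lognormal for the positive-activity regime); expression is `A·W` plus iid
Gaussian noise of sd `noise_sd`, optionally pushed through
`mean = 10·softplus(latent + 1)` into Poisson or gamma-Poisson counts.
Knockouts zero the activity columns of the perturbed TFs.  The genome
scaffold places one TSS per gene on a synthetic chromosome with spacing
`> 2·window + peak width`, so each generated peak can be assigned only to
its target gene; every surviving prior edge gets a peak containing a motif
occurrence of its TF, with false-negative (no peak, rate `prior_fnr`) and
decoy (false peak/hit, rate `prior_fpr`) corruption.  With both rates zero,
prior construction reconstructs the true support exactly — a closure
property the tests rely on.

**Edge signs.**  By default each TF is consistently an activator or a
repressor (`weight_mode="tf_signed"`, sign drawn per TF).  This is the
biologically common case and it is required for identifiability of the TFA
step: with signs drawn independently per edge (`"edge_signed"`, available
as an option), `W·P⁺` has a zero-mean random diagonal, so activities cannot
be recovered from an unsigned prior by any method — measured activity
correlations drop to ~0.3 and edge recovery collapses even though inference
from the true activities is perfect.  `"unit"` (all weights exactly 1)
gives the exact-model regime in which the pipeline is an identity map and
is used for the noiseless identifiability checks.

Defaults: 20 TFs, 400 genes, 3 regulators/gene, 300 samples per condition,
noise sd 0.25, prior corruption fnr 0.2 / fpr 0.02, one knocked-out TF.
These describe a mid-sized, well-powered design on which recovery tests run
in seconds; the noise-trend experiments use a reduced system (10 TFs,
100 genes, 120 samples per condition, 8 candidates per gene) so that 60
full pipeline runs stay cheap.  All randomness flows from one integer seed
through named substreams (NumPy PCG64), so equal seeds give bit-identical
bundles.

What the generator does *not* emulate: single-cell dropout beyond
Poisson/NB sampling, batch effects, TF–TF cooperativity, chromatin-state
dynamics, and sequence context beyond embedded consensus sites.  Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated model, not performance on real single-cell data.

## Known limitations

- TFA inversion assumes the prior is (approximately) the support of the
  true network up to the stated corruption; systematically signed-mismatched
  priors are unidentifiable (see above).
- Best-subset enumeration caps candidates at 20 (2²⁰ subsets); the default
  cap of 10 trades completeness for per-gene cost.
- The exact p-value DP is limited to motifs of length ≤ 20.
- R² = 1 is attainable only in the exact-model regime; with estimated
  activities and model-averaged weights the ceiling depends on noise and
  prior corruption.
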