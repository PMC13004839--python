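"""Motif/accessibility prior construction.

Three stages: score PWMs along peak sequences (log2 likelihood ratio versus
background, both strands, exact DP p-values), assign peaks to genes whose TSS
lies within a window of the peak midpoint, and combine motif occurrences with
the assignment into a TF x gene connectivity matrix with per-edge evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .types import (
    GeneAnnotation,
    GremnetError,
    Peak,
    PriorMatrix,
    PWM,
    ValidationError,
    _BASE_INDEX,
)

PSEUDOCOUNT = 1e-3
SCORE_BIN = 1e-3  # discretization step for the p-value DP
MAX_PVALUE_LENGTH = 20  # DP table refusal limit

_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass
class MotifHit:
    """One motif occurrence; ``start``/``stop`` are 0-based half-open offsets
    within the scanned sequence (always forward-strand coordinates)."""

    motif_id: str
    sequence_name: str
    start: int
    stop: int
    strand: str
    score: float
    pvalue: Optional[float] = None


def _log_odds(pwm: PWM) -> np.ndarray:
    """L x 4 log2 likelihood-ratio matrix with renormalized pseudocount."""
    p = (pwm.probs + PSEUDOCOUNT) / (1.0 + 4.0 * PSEUDOCOUNT)
    return np.log2(p / pwm.background[None, :])


def max_score(pwm: PWM) -> float:
    """Maximum attainable log-odds score (achieved by the consensus)."""
    return float(_log_odds(pwm).max(axis=1).sum())


def _discretize(lo: np.ndarray) -> np.ndarray:
    return np.round(lo / SCORE_BIN).astype(np.int64)


def score_distribution(pwm: PWM) -> tuple[np.ndarray, int]:
    """Exact distribution of the discretized log-odds score under the
    background model, by dynamic programming over positions.

    Returns ``(probs, offset)``: ``probs[i]`` is the probability that the
    discretized score equals ``i + offset`` (in SCORE_BIN units).
    """
    bins = _discretize(_log_odds(pwm))
    cur = np.array([1.0])
    cur_lo = 0
    for i in range(len(pwm)):
        row = bins[i]
        new_lo = cur_lo + int(row.min())
        new_hi = cur_lo + len(cur) - 1 + int(row.max())
        new = np.zeros(new_hi - new_lo + 1)
        for b in range(4):
            shift = cur_lo + int(row[b]) - new_lo
            new[shift : shift + len(cur)] += pwm.background[b] * cur
        cur, cur_lo = new, new_lo
    return cur, cur_lo


def pvalue_from_bin(b: int, dist: np.ndarray, offset: int) -> float:
    """P(discretized score >= bin ``b``) under the background."""
    idx = b - offset
    if idx <= 0:
        return 1.0
    if idx >= len(dist):
        return 0.0
    # suffix sum in index order; with dyadic backgrounds this is exact
    return float(np.sum(dist[idx:]))


def pvalue_from_score(score: float, dist: np.ndarray, offset: int) -> float:
    """P(discretized score >= discretized ``score``) under the background."""
    return pvalue_from_bin(int(np.round(score / SCORE_BIN)), dist, offset)


def scan_pwm(
    sequence: str,
    pwm: PWM,
    score_threshold: Optional[float] = None,
    pvalue_threshold: Optional[float] = None,
    sequence_name: str = "seq",
) -> list[MotifHit]:
    """Scan both strands of ``sequence`` for occurrences of ``pwm``.

    At each position the forward and reverse-complement scores are computed
    and the better strand is reported.  ``N`` contributes 0 to the score.
    Exactly one of ``score_threshold`` / ``pvalue_threshold`` must be given;
    p-values come from the exact discretized score distribution (motifs
    longer than 20 are refused in p-value mode).
    """
    if (score_threshold is None) == (pvalue_threshold is None):
        raise ValueError("give exactly one of score_threshold / pvalue_threshold")
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValidationError(f"invalid sequence characters: {sorted(bad)}")

    L = len(pwm)
    dist = off = None
    if pvalue_threshold is not None:
        if L > MAX_PVALUE_LENGTH:
            raise GremnetError(
                f"p-value mode supports motif length <= {MAX_PVALUE_LENGTH} "
                f"(got {L}); use a score threshold, or trim the motif"
            )
        dist, off = score_distribution(pwm)
        # smallest discretized score whose tail probability is <= threshold
        tail = np.cumsum(dist[::-1])[::-1]
        ok = np.nonzero(tail <= pvalue_threshold)[0]
        min_bin = (ok[0] + off) if ok.size else None

    lo = _log_odds(pwm)
    bins = _discretize(lo)
    rc = seq.translate(_COMP)[::-1]
    n = len(seq)
    hits: list[MotifHit] = []
    for pos in range(n - L + 1):
        fwd = _window_score(seq, pos, lo)
        # reverse-complement window covering the same positions
        rev = _window_score(rc, n - L - pos, lo)
        if fwd >= rev:
            s, strand = fwd, "+"
        else:
            s, strand = rev, "-"
        if pvalue_threshold is not None:
            # bin via the same per-position discretization the DP uses
            src, p0 = (seq, pos) if strand == "+" else (rc, n - L - pos)
            b = sum(
                int(bins[i, _BASE_INDEX[src[p0 + i]]])
                for i in range(L)
                if src[p0 + i] != "N"
            )
            if min_bin is None or b < min_bin:
                continue
            pv = pvalue_from_bin(b, dist, off)
            hits.append(MotifHit(pwm.motif_id, sequence_name, pos, pos + L, strand, s, pv))
        else:
            if s >= score_threshold:
                hits.append(MotifHit(pwm.motif_id, sequence_name, pos, pos + L, strand, s))
    return hits


def _window_score(seq: str, pos: int, lo: np.ndarray) -> float:
    s = 0.0
    for i in range(lo.shape[0]):
        b = seq[pos + i]
        if b != "N":
            s += lo[i, _BASE_INDEX[b]]
    return s


def assign_peaks_to_genes(
    peaks: list[Peak], genes: list[GeneAnnotation], window_bp: int
) -> dict[str, list[str]]:
    """Assign each peak to every gene whose TSS lies within ``window_bp`` of
    the peak midpoint (inclusive), on the same chromosome; strand-agnostic.

    Every peak appears in the result, possibly with an empty list.
    """
    if window_bp <= 0:
        raise ValidationError("window_bp must be positive")
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
    for lst in by_chrom.values():
        lst.sort()
    out: dict[str, list[str]] = {}
    for p in peaks:
        mid = p.midpoint
        matches: list[str] = []
        for tss, gid in by_chrom.get(p.chrom, []):
            if tss > mid + window_bp:
                break
            if abs(tss - mid) <= window_bp:
                matches.append(gid)
        out[p.peak_id] = matches
    return out


def build_prior(
    peaks: list[Peak],
    hits: list[MotifHit],
    assignment: dict[str, list[str]],
    motif_to_tf: dict[str, str],
    tf_ids: Optional[list[str]] = None,
    gene_ids: Optional[list[str]] = None,
    mode: str = "binary",
) -> PriorMatrix:
    """Combine motif occurrences in peaks with the peak-to-gene assignment.

    Entry (t, g) is nonzero iff some peak assigned to g contains at least one
    occurrence of a motif mapped to t; in weighted mode the entry is the
    total occurrence count.  Output is independent of input ordering.
    """
    if mode not in ("binary", "weighted"):
        raise ValueError(f"unknown prior mode {mode!r}")
    known_peaks = {p.peak_id for p in peaks}
    for h in hits:
        if h.sequence_name not in known_peaks:
            raise GremnetError(f"hit references unknown peak {h.sequence_name!r}")
        if h.motif_id not in motif_to_tf:
            raise GremnetError(f"no TF mapping for motif {h.motif_id!r}")

    if tf_ids is None:
        tf_ids = sorted(set(motif_to_tf.values()))
    if gene_ids is None:
        gene_ids = sorted({g for gl in assignment.values() for g in gl})
    ti = {t: i for i, t in enumerate(tf_ids)}
    gi = {g: i for i, g in enumerate(gene_ids)}

    values = np.zeros((len(tf_ids), len(gene_ids)))
    evidence: dict[tuple[str, str], list] = {}
    for h in sorted(hits, key=lambda h: (h.motif_id, h.sequence_name, h.start, h.strand)):
        tf = motif_to_tf[h.motif_id]
        if tf not in ti:
            continue
        for g in assignment.get(h.sequence_name, []):
            if g not in gi:
                continue
            values[ti[tf], gi[g]] += 1.0
            evidence.setdefault((tf, g), []).append(
                (h.sequence_name, h.motif_id, h.start, h.strand)
            )
    if mode == "binary":
        values = (values > 0).astype(float)
    return PriorMatrix(values, list(tf_ids), list(gene_ids), evidence)


def hits_from_scaffold(scaffold) -> list[MotifHit]:
    """Adapt a synthetic scaffold's (motif, peak, offset, strand) tuples to
    MotifHit records (score 0 placeholder; occurrences are by construction)."""
    L = {m.motif_id: len(m) for m in scaffold.pwms}
    return [
        MotifHit(mid, pid, off, off + L[mid], strand, 0.0)
        for (mid, pid, off, strand) in scaffold.motif_hits
    ]
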