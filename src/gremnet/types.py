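"""Core in-memory containers shared across the pipeline.

All matrices are dense numpy arrays with explicit id lists; orientation is
fixed throughout the package: expression is samples x genes, priors and
networks are TFs x genes, activities are samples x TFs.  Genomic coordinates
are 0-based half-open (BED convention) everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


class GremnetError(Exception):
    """Base class for all package errors."""


class FormatError(GremnetError):
    """Malformed input file (structure, duplicates, bad header)."""


class ValidationError(GremnetError):
    """Values violate a domain invariant."""


def _check_unique(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                raise FormatError(f"duplicate {what} id: {i!r}")
            seen.add(i)


@dataclass
class ExpressionMatrix:
    """Samples x genes numeric matrix.

    ``layer`` records the scale of ``values``: raw counts (non-negative
    integers) or log1p-normalized expression.
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    layer: str = "counts"  # counts | lognorm

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = list(self.sample_ids)
        self.gene_ids = list(self.gene_ids)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be 2-dimensional")
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.gene_ids, "gene")
        if self.layer not in ("counts", "lognorm"):
            raise ValidationError(f"unknown layer {self.layer!r}")
        if self.layer == "counts":
            if np.any(self.values < 0):
                s, g = np.argwhere(self.values < 0)[0]
                raise ValidationError(
                    f"negative count at sample {self.sample_ids[s]!r}, "
                    f"gene {self.gene_ids[g]!r}"
                )
            if not np.allclose(self.values, np.round(self.values)):
                raise ValidationError("counts layer requires integral entries")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), list(self.sample_ids), list(self.gene_ids), self.layer
        )


@dataclass
class GeneAnnotation:
    """TSS record for one gene; ``tss`` is a 0-based coordinate."""

    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValidationError(f"gene {self.gene_id}: tss must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass
class Peak:
    """Accessible-chromatin interval, 0-based half-open."""

    peak_id: str
    chrom: str
    start: int
    end: int
    stats: Optional[dict] = None  # optional log2fc / pvalue / fdr

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"peak {self.peak_id}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


@dataclass
class PWM:
    """Position probability matrix over ACGT with a background distribution."""

    motif_id: str
    tf_name: str
    probs: np.ndarray  # L x 4
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise ValidationError(f"motif {self.motif_id}: probs must be L x 4, L >= 1")
        rowsums = self.probs.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-6):
            bad = int(np.argmax(np.abs(rowsums - 1.0)))
            raise ValidationError(
                f"motif {self.motif_id}: row {bad} sums to {rowsums[bad]:.6g}, not 1"
            )
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValidationError(f"motif {self.motif_id}: background must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in np.argmax(self.probs, axis=1))


@dataclass
class DiffRecord:
    """One row of a differential expression / accessibility table."""

    feature_id: str
    log2fc: float
    pvalue: float
    padj: Optional[float]  # None when reported as NA

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValidationError(
                f"{self.feature_id}: pvalue {self.pvalue} outside [0, 1]"
            )
        if self.padj is not None and not (0.0 <= self.padj <= 1.0):
            raise ValidationError(f"{self.feature_id}: padj {self.padj} outside [0, 1]")


@dataclass
class PriorMatrix:
    """TFs x genes connectivity (binary by default) with per-edge evidence.

    ``evidence`` maps (tf_id, gene_id) to the list of (peak_id, motif_id,
    offset, strand) occurrences that support the edge; it may be empty for
    priors loaded from flat files or built synthetically.
    """

    values: np.ndarray
    tf_ids: list[str]
    gene_ids: list[str]
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.tf_ids = list(self.tf_ids)
        self.gene_ids = list(self.gene_ids)
        if self.values.shape != (len(self.tf_ids), len(self.gene_ids)):
            raise ValidationError("prior shape does not match id lists")
        _check_unique(self.tf_ids, "tf")
        _check_unique(self.gene_ids, "gene")
        if np.any(self.values < 0):
            raise ValidationError("prior entries must be >= 0")

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.values))

    def support(self) -> set[tuple[str, str]]:
        t, g = np.nonzero(self.values)
        return {(self.tf_ids[i], self.gene_ids[j]) for i, j in zip(t, g)}


@dataclass
class ActivityMatrix:
    """Samples x TFs latent activity estimates.

    ``method_tags`` records, per TF, whether the activity came from prior
    inversion (``inverted``) or from the TF's own expression
    (``self_expression``).
    """

    values: np.ndarray
    sample_ids: list[str]
    tf_ids: list[str]
    method_tags: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = list(self.sample_ids)
        self.tf_ids = list(self.tf_ids)
        if self.values.shape != (len(self.sample_ids), len(self.tf_ids)):
            raise ValidationError("activity shape does not match id lists")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.tf_ids, "tf")
        if np.any(~np.isfinite(self.values)):
            raise ValidationError("activity matrix contains NaN/inf")
        if self.method_tags is None:
            self.method_tags = ["inverted"] * len(self.tf_ids)


@dataclass
class NetworkMatrix:
    """Inferred GRN: signed TFs x genes weights with per-edge confidence."""

    weights: np.ndarray
    confidence: np.ndarray
    tf_ids: list[str]
    gene_ids: list[str]
    in_prior: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        self.tf_ids = list(self.tf_ids)
        self.gene_ids = list(self.gene_ids)
        shape = (len(self.tf_ids), len(self.gene_ids))
        if self.weights.shape != shape or self.confidence.shape != shape:
            raise ValidationError("network shape does not match id lists")
        _check_unique(self.tf_ids, "tf")
        _check_unique(self.gene_ids, "gene")
        if np.any(self.confidence < 0) or np.any(self.confidence > 1):
            raise ValidationError("confidence must lie in [0, 1]")
        if self.in_prior is None:
            self.in_prior = np.zeros(shape, dtype=bool)
        else:
            self.in_prior = np.asarray(self.in_prior, dtype=bool)
            if self.in_prior.shape != shape:
                raise ValidationError("in_prior shape does not match id lists")

    def support(self) -> set[tuple[str, str]]:
        t, g = np.nonzero(self.weights)
        return {(self.tf_ids[i], self.gene_ids[j]) for i, j in zip(t, g)}

    def best_model_support(self) -> set[tuple[str, str]]:
        """Edges selected into the per-gene best models (confidence > 0)."""
        t, g = np.nonzero(self.confidence)
        return {(self.tf_ids[i], self.gene_ids[j]) for i, j in zip(t, g)}
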