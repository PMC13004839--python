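"""Readers and writers for every external format the pipeline touches.

Formats: counts as TSV (samples x genes, header row of gene ids) or as a
1-based "row col value" triplet with companion id-list files; peaks as BED;
motifs as MEME minimal; differential tables, TSS tables, FIMO-style hit
tables, priors, activities and networks as TSV.

All floating-point output uses 12 significant digits and deterministic row
ordering so that repeated runs are byte-identical.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .types import (
    ActivityMatrix,
    DiffRecord,
    ExpressionMatrix,
    FormatError,
    GeneAnnotation,
    NetworkMatrix,
    Peak,
    PriorMatrix,
    PWM,
    ValidationError,
)

PathLike = Union[str, Path]

FLOAT_FMT = "%.12g"


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


# ---------------------------------------------------------------------------
# counts


def read_counts(
    path: PathLike,
    format: str = "tsv",
    sample_ids_path: Optional[PathLike] = None,
    gene_ids_path: Optional[PathLike] = None,
) -> ExpressionMatrix:
    """Read a counts matrix.

    ``tsv``: header row of gene ids, first column of sample ids.
    ``triplet``: header ``row col value`` with 1-based indices; sample and
    gene id lists come from companion files (default ``<path>.rows`` and
    ``<path>.cols``, one id per line).
    """
    path = Path(path)
    if format == "tsv":
        return _read_counts_tsv(path)
    if format == "triplet":
        rows_p = Path(sample_ids_path) if sample_ids_path else path.with_name(path.name + ".rows")
        cols_p = Path(gene_ids_path) if gene_ids_path else path.with_name(path.name + ".cols")
        return _read_counts_triplet(path, rows_p, cols_p)
    raise ValueError(f"unknown counts format {format!r}")


def _read_counts_tsv(path: Path) -> ExpressionMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        gene_ids = header.split("\t")
        if gene_ids and gene_ids[0] == "":
            gene_ids = gene_ids[1:]
        sample_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(gene_ids) + 1:
                raise FormatError(
                    f"{path}:{lineno}: expected {len(gene_ids) + 1} fields, "
                    f"got {len(parts)}"
                )
            sample_ids.append(parts[0])
            try:
                row = [float(v) for v in parts[1:]]
            except ValueError as e:
                raise ValidationError(f"{path}:{lineno}: non-numeric entry ({e})")
            for j, v in enumerate(row):
                if v < 0:
                    raise ValidationError(
                        f"{path}:{lineno}: negative count at sample "
                        f"{parts[0]!r}, gene {gene_ids[j]!r}"
                    )
            rows.append(row)
    if not rows:
        raise FormatError(f"{path}: no data rows")
    return ExpressionMatrix(np.array(rows), sample_ids, gene_ids, layer="counts")


def _read_id_list(path: Path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def _read_counts_triplet(path: Path, rows_p: Path, cols_p: Path) -> ExpressionMatrix:
    sample_ids = _read_id_list(rows_p)
    gene_ids = _read_id_list(cols_p)
    values = np.zeros((len(sample_ids), len(gene_ids)))
    with open(path) as fh:
        header = fh.readline().split()
        if header[:3] != ["row", "col", "value"]:
            raise FormatError(f"{path}: triplet header must be 'row col value'")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 fields")
            try:
                r, c = int(parts[0]), int(parts[1])
                v = float(parts[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric triplet entry")
            if not (1 <= r <= len(sample_ids) and 1 <= c <= len(gene_ids)):
                raise ValidationError(f"{path}:{lineno}: index ({r},{c}) out of range")
            if v < 0:
                raise ValidationError(
                    f"{path}:{lineno}: negative count at sample "
                    f"{sample_ids[r - 1]!r}, gene {gene_ids[c - 1]!r}"
                )
            values[r - 1, c - 1] = v
    return ExpressionMatrix(values, sample_ids, gene_ids, layer="counts")


def write_counts(x: ExpressionMatrix, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join([""] + x.gene_ids) + "\n")
        for i, sid in enumerate(x.sample_ids):
            fh.write("\t".join([sid] + [_fmt(v) for v in x.values[i]]) + "\n")


def read_expression_tsv(path: PathLike, layer: str = "lognorm") -> ExpressionMatrix:
    """Read a samples x genes TSV into the given layer (no count validation)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        df.to_numpy(dtype=float), [str(s) for s in df.index], [str(g) for g in df.columns], layer=layer
    )


# ---------------------------------------------------------------------------
# BED peaks


def read_bed_peaks(path: PathLike) -> list[Peak]:
    """Read peaks from a BED file (>= 3 columns; optional 4th is the id)."""
    peaks: list[Peak] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate")
            if start >= end:
                raise ValidationError(
                    f"{path}:{lineno}: empty or inverted interval [{start}, {end})"
                )
            peak_id = parts[3] if len(parts) >= 4 and parts[3] else f"{chrom}:{start}-{end}"
            if peak_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate peak id {peak_id!r}")
            seen.add(peak_id)
            peaks.append(Peak(peak_id, chrom, start, end))
    return peaks


def write_bed_peaks(peaks: list[Peak], path: PathLike) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\n")


# ---------------------------------------------------------------------------
# MEME minimal motifs


def read_meme_motifs(path: PathLike) -> list[PWM]:
    """Parse a MEME minimal-format motif file into PWMs.

    The background comes from the ``Background letter frequencies`` line when
    present, otherwise it is uniform.  A probability row off unity by more
    than 1e-3 is rejected.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    background = np.full(4, 0.25)
    motifs: list[PWM] = []
    i = 0
    saw_version = False
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MEME version"):
            saw_version = True
        elif line.startswith("ALPHABET"):
            alpha = line.split("=", 1)[1].strip() if "=" in line else ""
            if alpha.replace(" ", "") != "ACGT":
                raise FormatError(
                    f"{path}: unsupported alphabet {alpha!r}; only ACGT is handled"
                )
        elif line.startswith("Background letter frequencies"):
            i += 1
            tokens = lines[i].split()
            freq = {tokens[j]: float(tokens[j + 1]) for j in range(0, len(tokens), 2)}
            background = np.array([freq.get(b, 0.25) for b in "ACGT"])
        elif line.startswith("MOTIF"):
            fields = line.split()
            motif_id = fields[1]
            tf_name = fields[2] if len(fields) > 2 else motif_id.split("_")[0]
            # advance to the letter-probability header
            j = i + 1
            while j < len(lines) and not lines[j].strip().startswith(
                "letter-probability matrix"
            ):
                if lines[j].strip().startswith("MOTIF"):
                    raise FormatError(
                        f"{path}: motif {motif_id} has no letter-probability matrix"
                    )
                j += 1
            if j >= len(lines):
                raise FormatError(
                    f"{path}: motif {motif_id} has no letter-probability matrix"
                )
            rows = []
            j += 1
            while j < len(lines):
                s = lines[j].strip()
                if not s or s.startswith(("MOTIF", "URL")):
                    break
                vals = [float(v) for v in s.split()]
                if len(vals) != 4:
                    raise FormatError(
                        f"{path}:{j + 1}: expected 4 probabilities, got {len(vals)}"
                    )
                if abs(sum(vals) - 1.0) > 1e-3:
                    raise ValidationError(
                        f"{path}:{j + 1}: motif {motif_id} row sums to "
                        f"{sum(vals):.6g}, not 1"
                    )
                rows.append(vals)
                j += 1
            probs = np.array(rows)
            probs = probs / probs.sum(axis=1, keepdims=True)  # fix 1e-3 slop
            motifs.append(PWM(motif_id, tf_name, probs, background))
            i = j - 1
        i += 1
    if not saw_version:
        raise FormatError(f"{path}: missing 'MEME version' header")
    return motifs


def write_meme_motifs(motifs: list[PWM], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        if motifs:
            bg = motifs[0].background
            fh.write("Background letter frequencies\n")
            fh.write(
                f"A {_fmt(bg[0])} C {_fmt(bg[1])} G {_fmt(bg[2])} T {_fmt(bg[3])}\n\n"
            )
        for m in motifs:
            fh.write(f"MOTIF {m.motif_id} {m.tf_name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(m)} "
                f"nsites= 20 E= 0\n"
            )
            for row in m.probs:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# differential tables

_DEFAULT_DIFF_COLS = {
    "feature_id": "feature_id",
    "log2fc": "log2fc",
    "pvalue": "pvalue",
    "padj": "padj",
}


def read_diff_table(
    path: PathLike,
    kind: str = "rna",
    columns: Optional[dict] = None,
    sep: str = "\t",
) -> list[DiffRecord]:
    """Read a DESeq2/edgeR-style differential table.

    ``columns`` maps the canonical names (feature_id, log2fc, pvalue, padj)
    to the header names in the file.  ``NA`` padj values become missing.
    """
    cols = dict(_DEFAULT_DIFF_COLS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep=sep)
    missing = [v for v in cols.values() if v not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing column(s) {missing}; found {list(df.columns)}"
        )
    records = []
    for _, row in df.iterrows():
        padj = row[cols["padj"]]
        padj = None if pd.isna(padj) else float(padj)
        records.append(
            DiffRecord(
                feature_id=str(row[cols["feature_id"]]),
                log2fc=float(row[cols["log2fc"]]),
                pvalue=float(row[cols["pvalue"]]),
                padj=padj,
            )
        )
    return records


def write_diff_table(records: list[DiffRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("feature_id\tlog2fc\tpvalue\tpadj\n")
        for r in records:
            padj = "NA" if r.padj is None else _fmt(r.padj)
            fh.write(f"{r.feature_id}\t{_fmt(r.log2fc)}\t{_fmt(r.pvalue)}\t{padj}\n")


# ---------------------------------------------------------------------------
# TSS annotation


def read_tss_table(path: PathLike) -> list[GeneAnnotation]:
    """Read a TSS table (gene_id, chrom, tss, strand); tss is 0-based."""
    df = pd.read_csv(path, sep="\t")
    needed = {"gene_id", "chrom", "tss", "strand"}
    if not needed.issubset(df.columns):
        raise FormatError(
            f"{path}: need columns {sorted(needed)}; found {list(df.columns)}"
        )
    return [
        GeneAnnotation(str(r.gene_id), str(r.chrom), int(r.tss), str(r.strand))
        for r in df.itertuples()
    ]


def write_tss_table(genes: list[GeneAnnotation], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\ttss\tstrand\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.tss}\t{g.strand}\n")


# ---------------------------------------------------------------------------
# FIMO-style motif hit tables


def read_hits_table(path: PathLike) -> pd.DataFrame:
    """Read a FIMO-style hits TSV: motif_id, sequence_name, start, stop, strand, score."""
    df = pd.read_csv(path, sep="\t")
    needed = {"motif_id", "sequence_name", "start", "stop", "strand", "score"}
    if not needed.issubset(df.columns):
        raise FormatError(
            f"{path}: need columns {sorted(needed)}; found {list(df.columns)}"
        )
    return df


def write_hits_table(df: pd.DataFrame, path: PathLike) -> None:
    out = df.sort_values(
        ["motif_id", "sequence_name", "start", "strand"], kind="mergesort"
    )
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# prior / activity / network matrices


def write_prior(prior: PriorMatrix, path: PathLike) -> None:
    """Write a prior as long-format TSV (tf, gene, weight, n_peaks)."""
    with open(path, "w") as fh:
        fh.write("tf\tgene\tweight\tn_peaks\n")
        edges = sorted(
            (prior.tf_ids[i], prior.gene_ids[j], prior.values[i, j])
            for i, j in zip(*np.nonzero(prior.values))
        )
        for tf, gene, w in edges:
            n_peaks = len({e[0] for e in prior.evidence.get((tf, gene), [])})
            fh.write(f"{tf}\t{gene}\t{_fmt(w)}\t{n_peaks}\n")


def read_prior(
    path: PathLike,
    tf_ids: Optional[list[str]] = None,
    gene_ids: Optional[list[str]] = None,
) -> PriorMatrix:
    df = pd.read_csv(path, sep="\t")
    if not {"tf", "gene", "weight"}.issubset(df.columns):
        raise FormatError(f"{path}: need columns tf, gene, weight")
    if tf_ids is None:
        tf_ids = sorted(df["tf"].astype(str).unique())
    if gene_ids is None:
        gene_ids = sorted(df["gene"].astype(str).unique())
    ti = {t: i for i, t in enumerate(tf_ids)}
    gi = {g: i for i, g in enumerate(gene_ids)}
    values = np.zeros((len(tf_ids), len(gene_ids)))
    for r in df.itertuples():
        t, g = str(r.tf), str(r.gene)
        if t in ti and g in gi:
            values[ti[t], gi[g]] = float(r.weight)
    return PriorMatrix(values, tf_ids, gene_ids)


def write_activities(a: ActivityMatrix, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join([""] + a.tf_ids) + "\n")
        for i, sid in enumerate(a.sample_ids):
            fh.write("\t".join([sid] + [_fmt(v) for v in a.values[i]]) + "\n")


def read_activities(path: PathLike) -> ActivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ActivityMatrix(
        df.to_numpy(dtype=float), [str(s) for s in df.index], [str(t) for t in df.columns]
    )


def write_network(network: NetworkMatrix, path: PathLike) -> None:
    """Write nonzero network edges as TSV (tf, gene, weight, confidence, in_prior).

    Rows are ordered tf-then-gene lexicographically; two runs on the same
    network yield byte-identical files.
    """
    mask = (network.weights != 0) | (network.confidence != 0)
    edges = sorted(
        (
            network.tf_ids[i],
            network.gene_ids[j],
            network.weights[i, j],
            network.confidence[i, j],
            bool(network.in_prior[i, j]),
        )
        for i, j in zip(*np.nonzero(mask))
    )
    with open(path, "w") as fh:
        fh.write("tf\tgene\tweight\tconfidence\tin_prior\n")
        for tf, gene, w, c, inp in edges:
            fh.write(f"{tf}\t{gene}\t{_fmt(w)}\t{_fmt(c)}\t{int(inp)}\n")


def read_network(
    path: PathLike,
    tf_ids: Optional[list[str]] = None,
    gene_ids: Optional[list[str]] = None,
) -> NetworkMatrix:
    df = pd.read_csv(path, sep="\t")
    if not {"tf", "gene", "weight", "confidence"}.issubset(df.columns):
        raise FormatError(f"{path}: need columns tf, gene, weight, confidence")
    if tf_ids is None:
        tf_ids = sorted(df["tf"].astype(str).unique())
    if gene_ids is None:
        gene_ids = sorted(df["gene"].astype(str).unique())
    ti = {t: i for i, t in enumerate(tf_ids)}
    gi = {g: i for i, g in enumerate(gene_ids)}
    shape = (len(tf_ids), len(gene_ids))
    weights = np.zeros(shape)
    confidence = np.zeros(shape)
    in_prior = np.zeros(shape, dtype=bool)
    for r in df.itertuples():
        t, g = str(r.tf), str(r.gene)
        if t in ti and g in gi:
            weights[ti[t], gi[g]] = float(r.weight)
            confidence[ti[t], gi[g]] = float(r.confidence)
            if hasattr(r, "in_prior"):
                in_prior[ti[t], gi[g]] = bool(int(r.in_prior))
    return NetworkMatrix(weights, confidence, tf_ids, gene_ids, in_prior)


# ---------------------------------------------------------------------------
# flat key=value config


def read_config(path: PathLike) -> dict[str, str]:
    """Read a flat ``key = value`` config file; '#' starts a comment."""
    cfg: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{lineno}: expected 'key = value'")
            k, v = line.split("=", 1)
            cfg[k.strip()] = v.strip()
    return cfg
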