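"""Bulk gene-expression preprocessing and signature encoding.

The pipeline mirrors standard bulk RNA-seq practice: drop low-signal genes
(zero interquartile range on the normalized scale, or a raw cumulative count
across samples <= 1), collapse duplicate gene symbols keeping the row with
the highest mean ("maxMean"), normalize to log2 counts-per-million with a
pseudo-count, then slice out per-signature expression vectors. A
trimmed-mean-of-M-values scaling hook can be plugged into :func:`log_cpm`
for real cohorts; the default is plain library-size CPM.

Gene symbol matching is case-sensitive exact string match. Signature genes
absent from the matrix are dropped with a warning (shrinking that
signature's vector); a signature matching nothing is an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyMatrixError, SignatureMatchError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix", "SignatureSet", "read_expression", "read_signature",
    "filter_genes", "collapse_duplicates", "log_cpm",
    "extract_signature_values", "encode_signatures",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix with raw-count bookkeeping.

    ``raw_totals`` (per-gene total raw counts) survives normalization so the
    cumulative-sum filter criterion stays evaluable — and idempotent — after
    log-CPM transformation.
    """

    values: pd.DataFrame
    normalized: bool = False
    raw_totals: pd.Series | None = None

    def __post_init__(self):
        if not self.normalized and (self.values.to_numpy() < 0).any():
            raise ConfigurationError("raw counts must be non-negative")
        if self.raw_totals is None:
            if self.normalized:
                raise ConfigurationError(
                    "normalized matrix requires stored raw_totals")
            self.raw_totals = self.values.sum(axis=1)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]


def read_expression(path) -> ExpressionMatrix:
    """Read a genes x samples CSV/TSV (first column gene symbols)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix(df)


def read_signature(path) -> list[str]:
    """One gene symbol per line; blank lines ignored."""
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


def filter_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Remove invariant or near-empty genes.

    A gene goes when its IQR across samples (on the normalized scale if the
    matrix is normalized) is zero, or its cumulative raw count is <= 1.
    Order of survivors is preserved; idempotent by construction.
    """
    if matrix.values.shape[1] < 2:
        raise ConfigurationError("gene filtering needs >= 2 samples")
    vals = matrix.values.to_numpy(dtype=float)
    q75, q25 = np.percentile(vals, [75, 25], axis=1)  # linear interpolation
    iqr_zero = (q75 - q25) == 0
    low_total = matrix.raw_totals.to_numpy(dtype=float) <= 1.0
    keep = ~(iqr_zero | low_total)
    if not keep.any():
        raise EmptyMatrixError("no genes survive filtering")
    return ExpressionMatrix(matrix.values.loc[keep], matrix.normalized,
                            matrix.raw_totals.loc[keep])


def collapse_duplicates(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse duplicate gene symbols keeping the highest-mean row."""
    means = matrix.values.mean(axis=1).to_numpy()
    order = np.arange(matrix.n_genes)
    best: dict[str, int] = {}
    for i, gene in zip(order, matrix.values.index):
        if gene not in best or means[i] > means[best[gene]]:
            best[gene] = i
    keep_idx = sorted(best.values())
    return ExpressionMatrix(matrix.values.iloc[keep_idx],
                            matrix.normalized,
                            matrix.raw_totals.iloc[keep_idx])


def log_cpm(matrix: ExpressionMatrix, prior_count: float = 0.5,
            scaling_hook=None) -> ExpressionMatrix:
    """log2 counts-per-million with a pseudo-count.

    value = log2((count + prior) / (library_size + 2*prior) * 1e6), with
    library_size the per-sample column sum. ``scaling_hook(matrix)`` may
    return per-sample scaling factors (e.g. TMM) multiplied into the
    library sizes; the default applies none.
    """
    if matrix.normalized:
        raise ConfigurationError("matrix is already normalized")
    if prior_count <= 0:
        raise ConfigurationError("prior_count must be positive")
    counts = matrix.values.to_numpy(dtype=float)
    if not np.isfinite(counts).all():
        raise ConfigurationError("counts must be finite")
    lib = counts.sum(axis=0)
    zero = lib == 0
    if zero.any():
        bad = [s for s, z in zip(matrix.sample_ids, zero) if z]
        raise ConfigurationError(f"zero library size for sample(s): {bad}")
    if scaling_hook is not None:
        lib = lib * np.asarray(scaling_hook(matrix), dtype=float)
    vals = np.log2((counts + prior_count) / (lib + 2.0 * prior_count) * 1e6)
    df = pd.DataFrame(vals, index=matrix.values.index,
                      columns=matrix.values.columns)
    return ExpressionMatrix(df, normalized=True, raw_totals=matrix.raw_totals)


def extract_signature_values(matrix: ExpressionMatrix,
                             gene_lists: dict[str, list[str]]
                             ) -> dict[str, list[np.ndarray]]:
    """Per-sample signature vectors S_i (gene-list order, missing dropped).

    Returns ``{sample_id: [S_1, ..., S_M]}``. Raises when a signature has no
    gene present in the matrix.
    """
    if not matrix.normalized:
        raise ConfigurationError("extract_signature_values needs a "
                                 "normalized matrix")
    present = set(matrix.values.index)
    matched: dict[str, list[str]] = {}
    for name, genes in gene_lists.items():
        found = [g for g in genes if g in present]
        missing = [g for g in genes if g not in present]
        if not found:
            raise SignatureMatchError(
                f"signature {name!r}: no genes found in matrix")
        if missing:
            logger.warning("signature %r: dropping %d missing gene(s): %s",
                           name, len(missing), missing)
        matched[name] = found
    out: dict[str, list[np.ndarray]] = {}
    for sample in matrix.sample_ids:
        col = matrix.values[sample]
        out[sample] = [col.loc[genes].to_numpy(dtype=float)
                       for genes in matched.values()]
    return out


def encode_signatures(values: list[np.ndarray],
                      embed_params: list[tuple[np.ndarray, np.ndarray]]
                      ) -> np.ndarray:
    """Affine per-signature encoding: row i of B = W_i @ S_i + b_i.

    ``embed_params[i]`` is a (W_i, b_i) pair with W_i of shape (D, P_i).
    All outputs share dimension D; the result is M x D.
    """
    if len(values) != len(embed_params):
        raise ConfigurationError(
            f"{len(values)} signature vectors vs {len(embed_params)} encoders")
    rows = []
    for i, (vec, (w, b)) in enumerate(zip(values, embed_params)):
        vec = np.asarray(vec, dtype=float)
        w = np.asarray(w, dtype=float)
        b = np.asarray(b, dtype=float)
        if w.shape[1] != vec.shape[0]:
            raise ConfigurationError(
                f"signature {i}: vector length {vec.shape[0]} != encoder "
                f"input {w.shape[1]}")
        rows.append(w @ vec + b)
    dims = {r.shape[0] for r in rows}
    if len(dims) > 1:
        raise ConfigurationError(f"embedding dims differ across signatures: {dims}")
    return np.stack(rows, axis=0)


@dataclass
class SignatureSet:
    """Named gene signatures with per-sample values and encoder params."""

    names: list[str]
    gene_lists: list[list[str]]
    values_per_sample: dict[str, list[np.ndarray]] = field(default_factory=dict)
    embed_params: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def __post_init__(self):
        if len(self.names) < 1:
            raise ConfigurationError("need at least one signature")
        if len(self.names) != len(self.gene_lists):
            raise ConfigurationError("names and gene_lists differ in length")
        if any(len(g) < 1 for g in self.gene_lists):
            raise ConfigurationError("each signature needs >= 1 gene")

    @property
    def n_signatures(self) -> int:
        return len(self.names)

    @classmethod
    def from_matrix(cls, matrix: ExpressionMatrix,
                    gene_lists: dict[str, list[str]]) -> "SignatureSet":
        values = extract_signature_values(matrix, gene_lists)
        return cls(names=list(gene_lists), gene_lists=list(gene_lists.values()),
                   values_per_sample=values)
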