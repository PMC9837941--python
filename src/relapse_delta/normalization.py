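"""Count normalization to the working expression scales.

Bulk analyses run on log2 RPKM (reads per kilobase per million mapped
reads, log-transformed with a pseudocount); deconvolution runs on linear
CPM.  Library size is always the within-matrix column sum — the pipeline
starts from count matrices, not aligner reports.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix_io import ExpressionMatrix, MatrixIOError


def _libsizes(counts: ExpressionMatrix) -> pd.Series:
    libsize = counts.values.sum(axis=0)
    zero = libsize[libsize == 0]
    if len(zero):
        raise MatrixIOError(f"zero library size for sample(s): {list(zero.index)[:5]}")
    return libsize


def log2_rpkm(
    counts: ExpressionMatrix,
    gene_info: pd.DataFrame,
    pseudocount: float = 1.0,
) -> ExpressionMatrix:
    """log2(count * 1e9 / (libsize * length_bp) + pseudocount), per cell.

    With the default pseudocount of 1 a zero count maps to exactly 0 and
    all outputs are finite.
    """
    if counts.scale != "counts":
        raise MatrixIOError(f"expected counts scale, got {counts.scale!r}")
    if pseudocount <= 0:
        raise MatrixIOError("pseudocount must be > 0")
    missing = [g for g in counts.gene_ids if g not in gene_info.index]
    if missing:
        raise MatrixIOError(f"genes without length annotation: {missing[:5]}")
    libsize = _libsizes(counts)
    lengths = gene_info.loc[counts.gene_ids, "length_bp"].astype(float)
    rpkm = counts.values.mul(1e9).div(libsize, axis=1).div(lengths, axis=0)
    return ExpressionMatrix(np.log2(rpkm + pseudocount), scale="log2rpkm")


def cpm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Counts per million: column-normalized to 1e6 (linear scale)."""
    if counts.scale != "counts":
        raise MatrixIOError(f"expected counts scale, got {counts.scale!r}")
    libsize = _libsizes(counts)
    return ExpressionMatrix(counts.values.mul(1e6).div(libsize, axis=1), scale="cpm")


def filter_low_expression(mat: ExpressionMatrix, min_mean: float) -> ExpressionMatrix:
    """Keep genes whose row mean is >= ``min_mean``; preserves gene order."""
    keep = mat.values.mean(axis=1) >= min_mean
    if not keep.any():
        raise MatrixIOError(f"no genes pass mean-expression filter {min_mean}")
    return ExpressionMatrix(mat.values[keep], scale=mat.scale)
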