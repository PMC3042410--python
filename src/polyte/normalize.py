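"""Probe-level normalization and gene-level summarization.

Implements the RMA-style core used for polysome-profiling arrays: quantile
normalization across arrays, log2 transform, Tukey median-polish
summarization of probes into per-gene expression values, and averaging of
technical replicate arrays.  Background correction is deliberately omitted
(it belongs to scanner vendor software and synthetic inputs need none).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "quantile_normalize",
    "median_polish",
    "median_polish_summarize",
    "summarize_tech_reps",
]

LINEAR = "linear"
LOG2 = "log2"


@dataclass
class ExpressionMatrix:
    """An intensity matrix (rows = probes or genes, columns = arrays/groups).

    Parameters
    ----------
    data
        DataFrame of intensities.  Strictly positive when ``scale`` is
        ``"linear"``; any real values when ``"log2"``.
    scale
        ``"linear"`` or ``"log2"``.
    gene_map
        For probe-level matrices, a Series mapping each row id (probe) to
        its gene id.  ``None`` for gene-level matrices.
    """

    data: pd.DataFrame
    scale: str = LINEAR
    gene_map: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.scale not in (LINEAR, LOG2):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        if self.data.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate array ids: {dup}")
        if self.scale == LINEAR and (self.data.to_numpy() <= 0).any():
            raise ValueError("linear-scale intensities must be strictly positive")
        if self.gene_map is not None and not self.gene_map.index.equals(self.data.index):
            raise ValueError("gene_map index must match matrix rows")

    def to_log2(self) -> "ExpressionMatrix":
        if self.scale == LOG2:
            return self
        return replace(self, data=np.log2(self.data), scale=LOG2)

    def to_linear(self) -> "ExpressionMatrix":
        if self.scale == LINEAR:
            return self
        return replace(self, data=2.0 ** self.data, scale=LINEAR)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every array to share one intensity distribution by rank.

    The reference distribution is the across-array mean of the sorted
    columns; each column's values are replaced by the reference value at
    their rank.  Ties receive the mean of the tied reference values
    (fractional ranks are linearly interpolated into the reference).
    Within-column rank order is preserved.
    """
    x = matrix.data.to_numpy(dtype=float)
    n_rows, n_cols = x.shape
    if n_cols == 1:
        return matrix
    reference = np.mean(np.sort(x, axis=0), axis=1)
    out = np.empty_like(x)
    positions = np.arange(1, n_rows + 1, dtype=float)
    from scipy.stats import rankdata

    for j in range(n_cols):
        ranks = rankdata(x[:, j], method="average")
        # fractional ranks from ties -> interpolate between reference values
        out[:, j] = np.interp(ranks, positions, reference)
    return replace(
        matrix, data=pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns)
    )


def scale_arrays(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Scale every array to the same average log2 intensity (the grand
    mean of the per-array means).

    This is the conventional array-scaling step: a per-array multiplicative
    factor (additive in log space) that removes residual scale differences
    between arrays — including between array groups that were quantile
    normalized separately.  Arrays that already share a common mean are
    returned unchanged.
    """
    work = matrix.to_log2()
    col_means = work.data.mean(axis=0)
    centered = work.data - col_means + col_means.mean()
    out = replace(work, data=centered)
    return out if matrix.scale == LOG2 else out.to_linear()


def median_polish(
    x: np.ndarray, tol: float = 1e-6, max_iter: int = 20
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Fit the additive model x[i,j] = overall + row[i] + col[j] + resid[i,j]
    by iterative row/column median sweeps (Tukey).

    Returns ``(overall, row_effects, col_effects, residuals)``.  Iteration
    stops when the maximum absolute change in the residual matrix between
    sweeps is <= ``tol``, or after ``max_iter`` full sweeps.
    """
    resid = np.asarray(x, dtype=float).copy()
    n_rows, n_cols = resid.shape
    overall = 0.0
    row = np.zeros(n_rows)
    col = np.zeros(n_cols)
    for _ in range(max_iter):
        prev = resid.copy()
        rm = np.median(resid, axis=1)
        resid -= rm[:, None]
        row += rm
        delta = np.median(col)
        col -= delta
        overall += delta
        cm = np.median(resid, axis=0)
        resid -= cm[None, :]
        col += cm
        delta = np.median(row)
        row -= delta
        overall += delta
        if np.max(np.abs(resid - prev)) <= tol:
            break
    return overall, row, col, resid


def _median_polish_blocks(x3: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    """Median polish applied to a stack of equally-shaped gene blocks
    (genes x probes x arrays); returns per-gene array summaries
    ``overall + array_effect``.  Sweeps run until every block's residuals
    have stabilized, so results agree with the per-gene sweep up to the
    tolerance."""
    resid = x3.copy()
    n_g, n_p, n_a = resid.shape
    overall = np.zeros(n_g)
    row = np.zeros((n_g, n_p))
    col = np.zeros((n_g, n_a))
    for _ in range(max_iter):
        prev = resid.copy()
        rm = np.median(resid, axis=2)
        resid -= rm[:, :, None]
        row += rm
        delta = np.median(col, axis=1)
        col -= delta[:, None]
        overall += delta
        cm = np.median(resid, axis=1)
        resid -= cm[:, None, :]
        col += cm
        delta = np.median(row, axis=1)
        row -= delta[:, None]
        overall += delta
        if np.max(np.abs(resid - prev)) <= tol:
            break
    return overall[:, None] + col


def median_polish_summarize(
    matrix: ExpressionMatrix,
    probe_map: pd.Series | None = None,
    tol: float = 1e-6,
    max_iter: int = 20,
) -> ExpressionMatrix:
    """Summarize a log2 probe-level matrix into one expression value per
    gene and array.

    For each gene the probes-by-arrays block is median-polished and the
    per-array summary is ``overall + array_effect`` (probe affinities are
    absorbed into row effects and cancel).  Genes with a single probe pass
    through unchanged, by construction of the sweep.
    """
    if matrix.scale != LOG2:
        raise ValueError("median polish requires a log2-scale matrix")
    if probe_map is None:
        probe_map = matrix.gene_map
    if probe_map is None:
        raise ValueError("probe-to-gene map required")
    probe_map = probe_map.reindex(matrix.data.index)
    if probe_map.isna().any():
        missing = probe_map.index[probe_map.isna()].tolist()[:5]
        raise ValueError(f"probes without gene assignment: {missing} ...")

    arrays = matrix.data.columns
    x = matrix.data.to_numpy(dtype=float)
    order = np.argsort(probe_map.to_numpy(), kind="stable")
    genes_sorted = probe_map.to_numpy()[order]
    uniq, starts = np.unique(genes_sorted, return_index=True)
    bounds = np.append(starts, len(genes_sorted))

    sizes = np.diff(bounds)
    if len(np.unique(sizes)) == 1:
        # uniform probe count: polish all genes at once (G, P, A)
        blocks = x[order].reshape(len(uniq), sizes[0], len(arrays))
        summaries = _median_polish_blocks(blocks, tol=tol, max_iter=max_iter)
    else:
        summaries = np.empty((len(uniq), len(arrays)))
        for k in range(len(uniq)):
            rows = order[bounds[k] : bounds[k + 1]]
            overall, _, col, _ = median_polish(x[rows], tol=tol, max_iter=max_iter)
            summaries[k] = overall + col
    out = pd.DataFrame(summaries, index=pd.Index(uniq, name="gene_id"), columns=arrays)
    return ExpressionMatrix(out, scale=LOG2)


def summarize_tech_reps(
    matrix: ExpressionMatrix, sheet: pd.DataFrame, linear: bool = True
) -> ExpressionMatrix:
    """Average technical replicate arrays into one column per
    (strain, fraction, project) group.

    Averaging is done on the linear intensity scale by default (the TE is a
    ratio of linear intensity values); set ``linear=False`` to average on
    the log2 scale instead.  Output columns are a MultiIndex
    (strain, fraction, project); output scale matches the input scale.
    """
    missing = set(matrix.data.columns) - set(sheet["array_id"])
    if missing:
        raise ValueError(f"arrays absent from sample sheet: {sorted(missing)}")
    extra = set(sheet["array_id"]) - set(matrix.data.columns)
    if extra:
        raise ValueError(f"sample sheet references missing array columns: {sorted(extra)}")

    in_scale = matrix.scale
    work = matrix.to_linear() if linear else matrix.to_log2()
    groups = sheet.groupby(["strain", "fraction", "project"], sort=True)
    cols, names = [], []
    for key, grp in groups:
        if grp.empty:  # pragma: no cover - groupby never yields empty
            raise ValueError(f"empty replicate group {key}")
        cols.append(work.data[grp["array_id"].tolist()].mean(axis=1))
        names.append(key)
    out = pd.concat(cols, axis=1)
    out.columns = pd.MultiIndex.from_tuples(names, names=["strain", "fraction", "project"])
    summarized = ExpressionMatrix(out, scale=work.scale)
    return summarized.to_log2() if in_scale == LOG2 else summarized.to_linear()
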