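"""Quality filtering, CPM log-normalization and bimodal expression gating.

The gating logic implements the IFNG-positivity convention used throughout the
analysis: per-gene expression distributions in log2-normalized CPM are bimodal
(a detection/noise mode near zero and an expressing mode), and a cell is called
positive when its value strictly exceeds the density valley between the two
modes (0.2 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

DEFAULT_BINARIZE_THRESHOLD = 0.2

#: Gene-symbol prefixes removed before analysis (mitochondrial, ribosomal).
DEFAULT_EXCLUDE_PREFIXES = ("MT-", "RPL", "RPS", "MRPL", "MRPS")


@dataclass
class CellTable:
    """Cells x genes log2-normalized CPM expression with per-cell metadata.

    ``metadata`` is indexed by cell id and carries at least ``patient_id`` and
    ``tissue`` (``tumor``/``normal``); ``subtype`` (``MSI``/``MSS``) and a
    free-text ``subpopulation`` label are optional. ``ifng_positive`` is derived
    by :func:`binarize` on the IFNG column.
    """

    expression: pd.DataFrame
    metadata: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.metadata is None:
            self.metadata = pd.DataFrame(index=self.expression.index)
        if (self.expression.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.expression.index.duplicated().any():
            raise ValueError("duplicate cell ids in expression matrix")
        if not self.expression.index.equals(self.metadata.index):
            self.metadata = self.metadata.reindex(self.expression.index)
        for col in ("patient_id", "tissue"):
            if col in self.metadata.columns and self.metadata[col].isna().any():
                raise ValueError(f"every cell must have a {col}")

    @property
    def cell_ids(self) -> pd.Index:
        return self.expression.index

    def subset(self, mask) -> "CellTable":
        return CellTable(self.expression.loc[mask], self.metadata.loc[mask])

    def ifng_positive(self, threshold: float = DEFAULT_BINARIZE_THRESHOLD) -> pd.Series:
        if "IFNG" not in self.expression.columns:
            raise KeyError("IFNG not among measured genes")
        return binarize(self.expression["IFNG"], threshold)


def filter_genes_by_pattern(counts: pd.DataFrame,
                            prefixes=DEFAULT_EXCLUDE_PREFIXES) -> pd.DataFrame:
    """Drop genes whose symbol starts with any of the configured prefixes."""
    keep = [g for g in counts.columns if not str(g).startswith(tuple(prefixes))]
    return counts[keep]


def filter_cells(raw_counts: pd.DataFrame, min_genes: int = 200,
                 min_reads: int = 1000) -> pd.DataFrame:
    """QC-filter a cells x genes raw count matrix.

    A cell is retained when it has *more than* ``min_genes`` genes detected and
    *more than* ``min_reads`` total reads (strict inequalities). Genes with zero
    counts in every retained cell are removed; the order of surviving cells is
    preserved.
    """
    counts = raw_counts.to_numpy()
    genes_detected = (counts > 0).sum(axis=1)
    total_reads = counts.sum(axis=1)
    keep = (genes_detected > min_genes) & (total_reads > min_reads)
    if not keep.any():
        raise ValueError("no cells pass QC "
                         f"(min_genes={min_genes}, min_reads={min_reads})")
    out = raw_counts.loc[keep]
    nonzero_genes = out.columns[(out.to_numpy() > 0).any(axis=0)]
    return out[nonzero_genes]


def normalize_log2(counts: pd.DataFrame, scale: float = 1e6) -> pd.DataFrame:
    """Scale each cell to ``scale`` total counts, then log2(1 + x).

    With the default ``scale`` of 1e6 this yields log2-normalized CPM, the scale
    on which the 0.2 positivity threshold is defined.
    """
    totals = counts.sum(axis=1).to_numpy(dtype=float)
    if (totals <= 0).any():
        bad = counts.index[totals <= 0].tolist()
        raise ValueError(f"cells with zero total counts cannot be normalized: {bad}")
    scaled = counts.to_numpy(dtype=float) / totals[:, None] * scale
    return pd.DataFrame(np.log2(1.0 + scaled), index=counts.index,
                        columns=counts.columns)


def detect_bimodal_threshold(values, fallback: float = DEFAULT_BINARIZE_THRESHOLD,
                             grid_size: int = 512) -> float:
    """Locate the density valley between the two highest modes of ``values``.

    A Gaussian kernel-density estimate is evaluated on a grid; the threshold is
    the position of the density minimum between the two highest local maxima.
    If the distribution is unimodal (or degenerate), the configured ``fallback``
    is returned with a warning.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 100:
        raise ValueError("need at least 100 values to estimate a bimodal threshold")
    if np.ptp(vals) == 0:
        warnings.warn("constant input; returning fallback threshold", UserWarning)
        return fallback
    kde = gaussian_kde(vals)
    grid = np.linspace(vals.min(), vals.max(), grid_size)
    dens = kde(grid)
    # interior local maxima
    peaks = np.where((dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:]))[0] + 1
    if grid[0] == vals.min() and dens[0] > dens[1]:
        peaks = np.r_[0, peaks]
    if dens[-1] > dens[-2]:
        peaks = np.r_[peaks, grid_size - 1]
    # a genuine second mode must carry appreciable density, not a KDE wiggle
    if len(peaks) >= 2:
        heights = np.sort(dens[peaks])[::-1]
        if heights[1] < 0.05 * heights[0]:
            peaks = peaks[dens[peaks] == heights[0]]
    if len(peaks) < 2:
        warnings.warn("unimodal distribution; returning fallback threshold",
                      UserWarning)
        return fallback
    top2 = peaks[np.argsort(dens[peaks])[-2:]]
    lo, hi = int(top2.min()), int(top2.max())
    valley = lo + int(np.argmin(dens[lo:hi + 1]))
    return float(grid[valley])


def binarize(values, threshold: float) -> pd.Series | np.ndarray:
    """Strictly-greater-than binarization: value > threshold -> positive."""
    if not np.isfinite(threshold) and not np.isinf(threshold):
        raise ValueError("threshold must not be NaN")
    if isinstance(values, pd.Series):
        return values > threshold
    if isinstance(values, pd.DataFrame):
        return values > threshold
    return np.asarray(values) > threshold
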