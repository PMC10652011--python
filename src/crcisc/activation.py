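"""TCR-activation vs bystander-activation axis scoring for IFNG+ CD8+ T cells.

Each cell is scored by the Spearman correlation of its expression over a
signature gene panel against two reference centroids: the average expression
profile of experimentally TCR-activated T cells and of bystander-activated T
cells. Cells are then partitioned into four quadrants around a reference center
derived from normal-adjacent tissue cells, and the difference of median
correlations gives a directionality statistic (|d| < 0.2 is non-directional).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

NON_DIRECTIONAL_BAND = 0.2


@dataclass
class ReferenceCenter:
    """Per-axis center (e.g. mean scores of normal-adjacent tissue cells)."""

    center_tcr: float
    center_bys: float
    source: str = "normal-adjacent tissue"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.center_tcr) and np.isfinite(self.center_bys)):
            raise ValueError("reference center must be finite")


def _spearman_to_centroid(matrix: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    """Row-wise Spearman correlation of ``matrix`` rows against ``centroid``."""
    ranks = np.apply_along_axis(rankdata, 1, matrix)
    c_ranks = rankdata(centroid)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    c = c_ranks - c_ranks.mean()
    denom = np.sqrt((ranks ** 2).sum(axis=1) * (c ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return (ranks @ c) / denom


def score_activation(expression: pd.DataFrame, signature_genes,
                     tcr_centroid: pd.Series,
                     bystander_centroid: pd.Series) -> pd.DataFrame:
    """Per-cell rank correlations to the TCR and bystander centroids.

    Returns a frame indexed by cell id with columns ``r_tcr`` and ``r_bys`` in
    [-1, 1]. Cells constant over the signature genes get missing scores.
    """
    genes = [g for g in signature_genes
             if g in expression.columns and g in tcr_centroid.index
             and g in bystander_centroid.index]
    if len(genes) < 3:
        raise ValueError("need at least 3 shared signature genes")
    mat = expression[genes].to_numpy(dtype=float)
    r_tcr = _spearman_to_centroid(mat, tcr_centroid[genes].to_numpy(dtype=float))
    r_bys = _spearman_to_centroid(mat, bystander_centroid[genes].to_numpy(dtype=float))
    n_bad = int(np.isnan(r_tcr).sum())
    if n_bad:
        warnings.warn(f"{n_bad} cells constant over signature genes; scores missing",
                      UserWarning)
    return pd.DataFrame({"r_tcr": r_tcr, "r_bys": r_bys}, index=expression.index)


def directionality(scores_tcr, scores_bys,
                   band: float = NON_DIRECTIONAL_BAND) -> tuple[float, str]:
    """median(r_tcr) - median(r_bys) and its classification.

    Positive values mark TCR-directed populations, negative bystander-directed;
    ``|difference| < band`` (default 0.2) is classified non-directional. The
    statistic is antisymmetric under swapping the two score vectors.
    """
    a = np.asarray(scores_tcr, dtype=float)
    b = np.asarray(scores_bys, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("empty score vector")
    diff = float(np.median(a) - np.median(b))
    if abs(diff) < band:
        label = "non-directional"
    elif diff > 0:
        label = "TCR-directed"
    else:
        label = "bystander-directed"
    return diff, label


def quadrant_partition(scores: pd.DataFrame, reference: ReferenceCenter
                       ) -> tuple[pd.Series, pd.DataFrame]:
    """Assign each cell to a quadrant around the reference center.

    Labels are two letters, TCR axis first: ``HL`` means TCR-high /
    bystander-low. High requires a *strictly* greater score than the center, so
    cells exactly at the center fall in ``LL``. Returns the label series and a
    2x2 count table (rows: TCR level, columns: bystander level).
    """
    tcr_high = scores["r_tcr"] > reference.center_tcr
    bys_high = scores["r_bys"] > reference.center_bys
    labels = pd.Series(
        [("H" if t else "L") + ("H" if b else "L")
         for t, b in zip(tcr_high, bys_high)],
        index=scores.index, name="quadrant")
    counts = pd.DataFrame(0, index=["tcr_H", "tcr_L"], columns=["bys_H", "bys_L"])
    for lab, n in labels.value_counts().items():
        counts.loc[f"tcr_{lab[0]}", f"bys_{lab[1]}"] = int(n)
    return labels, counts


def reference_center(scores: pd.DataFrame,
                     source: str = "normal-adjacent tissue") -> ReferenceCenter:
    """Reference center as the per-axis mean of the given (normal-tissue) scores."""
    return ReferenceCenter(float(np.nanmean(scores["r_tcr"])),
                           float(np.nanmean(scores["r_bys"])), source)


def welch_test(a, b) -> tuple[float, float]:
    """Welch's unequal-variance two-sample t-test (two-sided).

    Implemented from the textbook formula with the Welch-Satterthwaite degrees
    of freedom; the two-sided p-value uses the t survival function.
    """
    from scipy.stats import t as t_dist  # p-value lookup only

    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = x.size, y.size
    se2 = vx / nx + vy / ny
    if se2 == 0:
        raise ValueError("zero variance in both groups")
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * float(t_dist.sf(abs(t), df))
    return float(t), min(p, 1.0)
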