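"""Tumor-reactive signaling module discovery and scoring.

Modules are gene sets discovered from the co-expression structure of the
39-gene tumor-reactive universe in IFNG+ CD8+ T cells: a Spearman correlation
matrix over genes is computed across cells, genes are embedded by their
correlation profiles, and hierarchical clustering of Euclidean distances
between those profiles is cut into ``k`` groups (five per subtype in the
canonical configuration).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from scipy.stats import rankdata

from .preprocess import DEFAULT_BINARIZE_THRESHOLD, binarize


def _spearman_matrix(expression: pd.DataFrame) -> np.ndarray:
    """Gene x gene Spearman correlation across cells (ties -> average ranks)."""
    ranks = np.apply_along_axis(rankdata, 0, expression.to_numpy(dtype=float))
    return np.corrcoef(ranks.T)


def discover_modules(expression: pd.DataFrame, genes=None, k: int = 5,
                     linkage: str = "complete") -> dict[str, list[str]]:
    """Partition genes into ``k`` co-expression modules.

    Parameters
    ----------
    expression:
        Cells x genes log-normalized expression (typically restricted to IFNG+
        cells).
    genes:
        Gene universe to partition (default: all columns).
    k:
        Number of modules to cut the tree into.

    Returns
    -------
    dict mapping ``module_1`` .. ``module_k`` to gene lists. The result is
    deterministic given the input and invariant to cell/gene order up to module
    relabeling.
    """
    genes = list(expression.columns) if genes is None else [g for g in genes]
    missing = set(genes) - set(expression.columns)
    if missing:
        raise KeyError(f"genes not in expression matrix: {sorted(missing)}")
    if k > len(genes):
        raise ValueError(f"k={k} exceeds number of genes ({len(genes)})")
    sub = expression[genes]
    variances = sub.to_numpy().var(axis=0)
    informative = [g for g, v in zip(genes, variances) if v > 0]
    degenerate = [g for g, v in zip(genes, variances) if v == 0]
    if len(informative) < 2:
        raise ValueError("need at least 2 genes with nonzero variance")
    corr = _spearman_matrix(sub[informative])
    dist = ssd.pdist(corr, metric="euclidean")
    tree = sch.linkage(dist, method=linkage)
    labels = sch.fcluster(tree, t=min(k, len(informative)), criterion="maxclust")

    assignment = dict(zip(informative, labels))
    if degenerate:
        warnings.warn(f"zero-variance genes assigned to nearest module: {degenerate}",
                      UserWarning)
        means = sub[informative].to_numpy().mean(axis=0)
        for g in degenerate:
            # nearest informative gene by mean expression; inherits its module
            nearest = informative[int(np.argmin(np.abs(means - sub[g].mean())))]
            assignment[g] = assignment[nearest]
    modules: dict[str, list[str]] = {}
    for label in sorted(set(assignment.values())):
        modules[f"module_{label}"] = sorted(
            g for g, l in assignment.items() if l == label)
    return modules


def partition_labels(modules: dict[str, list[str]], genes) -> np.ndarray:
    """Integer module label per gene (for comparing partitions, e.g. by ARI)."""
    lookup = {g: i for i, (name, gs) in enumerate(sorted(modules.items()))
              for g in gs}
    missing = [g for g in genes if g not in lookup]
    if missing:
        raise KeyError(f"genes not covered by partition: {missing}")
    return np.array([lookup[g] for g in genes])


def activation_map(expression: pd.DataFrame, modules: dict[str, list[str]],
                   groups: pd.Series,
                   threshold: float = DEFAULT_BINARIZE_THRESHOLD) -> pd.DataFrame:
    """Mean binarized expression per (cell group, module).

    Entry ``(g, m)`` is the mean over cells in group ``g`` and genes in module
    ``m`` of ``expr > threshold``; values lie in [0, 1]. Groups without cells
    yield missing values rather than zeros.
    """
    if groups.empty:
        raise ValueError("groups must be non-empty")
    declared = pd.unique(groups.dropna())
    groups = groups.reindex(expression.index)
    binary = binarize(expression, threshold).astype(float)
    rows = {}
    for name in declared:
        cells = binary.loc[groups == name]
        rows[name] = {
            m: (cells[gs].to_numpy().mean() if len(cells) else np.nan)
            for m, gs in modules.items()
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    return out[list(modules)]


def score_signature_binarized(expression: pd.DataFrame, gene_set,
                              threshold: float = DEFAULT_BINARIZE_THRESHOLD
                              ) -> pd.Series:
    """Per-cell mean of binarized expression over the signature genes."""
    present = [g for g in gene_set if g in expression.columns]
    missing = [g for g in gene_set if g not in expression.columns]
    if not present:
        raise KeyError(f"no signature gene measured; missing: {missing}")
    if missing:
        warnings.warn(f"signature genes not measured (ignored): {missing}",
                      UserWarning)
    return binarize(expression[present], threshold).mean(axis=1)


def metagene(expression: pd.DataFrame, gene_set) -> pd.Series:
    """Arithmetic mean of normalized expression over the set genes, per sample."""
    present = [g for g in gene_set if g in expression.columns]
    if not present:
        raise KeyError(f"no gene of the set is measured: {list(gene_set)}")
    return expression[present].mean(axis=1)


def module_overlap(module_sets: dict[str, list[str]]
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene presence/absence matrix and Jaccard similarity between modules.

    ``J(A, B) = |A n B| / |A u B|``; two empty sets have similarity 1, an empty
    vs a non-empty set 0.
    """
    if len(module_sets) < 2:
        raise ValueError("need at least 2 module sets")
    names = list(module_sets)
    universe = sorted(set().union(*(set(v) for v in module_sets.values())))
    presence = pd.DataFrame(
        [[g in set(module_sets[n]) for g in universe] for n in names],
        index=names, columns=universe).astype(int)
    jac = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            sa, sb = set(module_sets[a]), set(module_sets[b])
            union = sa | sb
            val = 1.0 if not union else len(sa & sb) / len(union)
            jac.iloc[i, j] = jac.iloc[j, i] = val
    return presence, jac
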