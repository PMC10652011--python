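"""Patient stratification into the Immune Subtype Classification (ISC).

Two levels are supported. At single-cell level, patients are clustered by
complete-linkage Euclidean hierarchical clustering of per-patient mean module
scores. At bulk level, per-signature patient-patient dissimilarities
(1 - Spearman over the signature's genes) are averaged across signatures and
partitioned by agglomerative clustering (Ward agglomeration on the precomputed
dissimilarity, k chosen by silhouette within 2..5 unless fixed). Clusters are
then named ISC1a/1b (MSI) or ISC2a-c / ISC3a-b (MSS) from their module
metagene profiles, and a feature-selected random-forest classifier transfers
the labels to external cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import silhouette_score
from sklearn.model_selection import RepeatedStratifiedKFold

MSI_LABELS = ["ISC1a", "ISC1b"]
MSS_LABELS = ["ISC2a", "ISC2b", "ISC2c", "ISC3a", "ISC3b"]


@dataclass
class PatientDistanceMatrix:
    """Per-signature and averaged symmetric patient-patient dissimilarities."""

    patients: list[str]
    per_signature: dict[str, pd.DataFrame]
    averaged: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        stack = np.stack([d.to_numpy() for d in self.per_signature.values()])
        avg = np.nanmean(stack, axis=0)
        self.averaged = pd.DataFrame(avg, index=self.patients,
                                     columns=self.patients)


def stratify_patients_sc(module_means: pd.DataFrame, n_clusters: int) -> pd.Series:
    """Cluster patients on per-patient mean module scores.

    Complete-linkage hierarchical clustering with Euclidean distances, cut at
    ``n_clusters`` (2 for MSI, 3 for MSS in the canonical analysis).
    """
    if n_clusters > len(module_means):
        raise ValueError("more clusters requested than patients")
    if not np.isfinite(module_means.to_numpy()).all():
        raise ValueError("module means must be finite")
    tree = sch.linkage(module_means.to_numpy(), method="complete",
                       metric="euclidean")
    labels = sch.fcluster(tree, t=n_clusters, criterion="maxclust")
    return pd.Series(labels, index=module_means.index, name="cluster")


def l1_normalize(expression: pd.DataFrame) -> pd.DataFrame:
    """Divide each patient's gene vector by its absolute sum (rows sum to 1)."""
    if (expression.to_numpy() < 0).any():
        raise ValueError("L1 normalization expects non-negative expression")
    totals = expression.abs().sum(axis=1)
    if (totals == 0).any():
        bad = expression.index[totals == 0].tolist()
        raise ValueError(f"zero-sum patients cannot be normalized: {bad}")
    return expression.div(totals, axis=0)


def patient_distance(expression: pd.DataFrame, module_genes) -> pd.DataFrame:
    """1 - Spearman correlation between patients over a signature's genes."""
    genes = [g for g in module_genes if g in expression.columns]
    if len(genes) < 3:
        raise ValueError(f"need >= 3 measured module genes, have {len(genes)}")
    sub = expression[genes].to_numpy(dtype=float)
    constant = sub.var(axis=1) == 0
    if constant.any():
        warnings.warn("constant patient vectors over module genes; "
                      "distances set to missing", UserWarning)
    ranks = np.apply_along_axis(rankdata, 1, sub)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (ranks @ ranks.T) / np.outer(norms, norms)
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=expression.index, columns=expression.index)


def compute_distance_matrices(expression: pd.DataFrame,
                              module_sets: dict[str, list[str]]
                              ) -> PatientDistanceMatrix:
    per_sig = {name: patient_distance(expression, genes)
               for name, genes in module_sets.items()}
    return PatientDistanceMatrix(list(expression.index), per_sig)


def isc_cluster(averaged_distance: pd.DataFrame, max_groups: int = 5,
                n_clusters: int | None = None) -> tuple[pd.Series, int]:
    """Agglomerative clustering on the averaged patient dissimilarity.

    Ward agglomeration on the precomputed dissimilarity (minimum-variance
    merges are far more robust to weak-signal outlier patients than single
    pair-mean linkages on rank-based distances); ``n_clusters`` fixes k,
    otherwise k is chosen in 2..max_groups by silhouette on the same
    dissimilarity. Deterministic.
    """
    d = averaged_distance.to_numpy()
    if d.shape[0] < 2:
        raise ValueError("need at least 2 patients")
    if np.allclose(d, d.flat[1] * (1 - np.eye(len(d)))):
        warnings.warn("all pairwise distances equal; returning a single cluster",
                      UserWarning)
        return pd.Series(0, index=averaged_distance.index, name="cluster"), 1
    condensed = ssd.squareform(d, checks=False)
    tree = sch.linkage(condensed, method="ward")

    def _fit(k: int) -> np.ndarray:
        return sch.fcluster(tree, t=k, criterion="maxclust")

    if n_clusters is not None:
        k, labels = n_clusters, _fit(n_clusters)
    else:
        best = None
        for k_try in range(2, min(max_groups, len(d) - 1) + 1):
            lab = _fit(k_try)
            if len(np.unique(lab)) < 2:
                continue
            score = silhouette_score(d, lab, metric="precomputed")
            if best is None or score > best[0]:
                best = (score, k_try, lab)
        _, k, labels = best
    return pd.Series(labels, index=averaged_distance.index, name="cluster"), int(k)


def label_isc(clusters: pd.Series, module_metagenes: pd.DataFrame,
              subtype: str) -> pd.Series:
    """Name clusters with ISC labels from their module-enrichment profiles.

    MSI: the cluster with the higher mean stem-like-progenitor metagene is
    ISC1a, the other ISC1b. MSS: clusters are ranked by overall mean module
    metagene; the inflamed side (up to 3 clusters above the largest gap in
    overall signal) becomes ISC2a >= ISC2b >= ISC2c by descending signal and the
    immune-silent side ISC3a >= ISC3b. Ties break on the long-term
    immunosurveillance metagene, then lexicographically by cluster id.
    """
    subtype = subtype.upper()
    clusters = clusters.reindex(module_metagenes.index)
    profile = module_metagenes.groupby(clusters).mean()

    def _module_col(fragment: str) -> str | None:
        hits = [c for c in module_metagenes.columns if fragment in c.lower()]
        return hits[0] if hits else None

    lti_col = _module_col("immunosurveillance")
    overall = profile.mean(axis=1)
    tiebreak = profile[lti_col] if lti_col else overall * 0

    order = sorted(profile.index,
                   key=lambda c: (-overall[c], -tiebreak[c], str(c)))
    if subtype == "MSI":
        stem_col = _module_col("stem")
        if stem_col is None:
            raise KeyError("no stem-like progenitor metagene column")
        if len(order) != 2:
            raise ValueError(f"MSI naming expects 2 clusters, got {len(order)}")
        order = sorted(profile.index,
                       key=lambda c: (-profile.loc[c, stem_col], -tiebreak[c],
                                      str(c)))
        mapping = {order[0]: "ISC1a", order[1]: "ISC1b"}
    elif subtype == "MSS":
        vals = overall[order].to_numpy()
        if len(order) == 1:
            mapping = {order[0]: "ISC2a"}
        else:
            gaps = vals[:-1] - vals[1:]
            # ISC2 side holds at most 3 clusters, ISC3 side at most 2
            lo = max(1, len(order) - 2)
            hi = min(3, len(order) - 1)
            split = lo + int(np.argmax(gaps[lo - 1:hi]))
            inflamed, silent = order[:split], order[split:]
            mapping = {c: f"ISC2{'abc'[i]}" for i, c in enumerate(inflamed)}
            mapping.update({c: f"ISC3{'ab'[i]}" for i, c in enumerate(silent)})
    else:
        raise ValueError(f"subtype must be MSI or MSS, got {subtype!r}")
    return clusters.map(mapping).rename("isc_label")


@dataclass
class ClassifierModel:
    """Feature-selected random forest for ISC label transfer."""

    selected_genes: list[str]
    forest: RandomForestClassifier
    classes: list[str]
    metadata: dict = field(default_factory=dict)


def select_features(X: pd.DataFrame, y, threshold: float = 0.001,
                    folds: int = 5, repeats: int = 3, seed: int = 12,
                    n_trees: int = 200) -> list[str]:
    """Genes whose cross-validated mean impurity-decrease importance > threshold.

    A random forest is trained on each fold of a repeated stratified k-fold
    split; impurity-decrease importances are averaged over all fold models and
    genes strictly above the threshold are retained.
    """
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError("every class needs at least `folds` samples")
    splitter = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats,
                                      random_state=seed)
    importances = np.zeros(X.shape[1])
    n_models = 0
    for train_idx, _ in splitter.split(X, y):
        forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                        class_weight="balanced")
        forest.fit(X.iloc[train_idx], y[train_idx])
        importances += forest.feature_importances_
        n_models += 1
    importances /= n_models
    selected = [g for g, imp in zip(X.columns, importances) if imp > threshold]
    if not selected:
        raise ValueError("no gene passes the importance threshold; "
                         "consider lowering it")
    return selected


def train_classifier(X: pd.DataFrame, y, selected_genes=None,
                     n_trees: int = 5000, seed: int = 12,
                     class_weighting: str = "balanced") -> ClassifierModel:
    """Fit the final random forest on the selected genes."""
    genes = list(selected_genes) if selected_genes is not None else list(X.columns)
    missing = [g for g in genes if g not in X.columns]
    if missing:
        raise KeyError(f"selected genes absent from training data: {missing}")
    y = np.asarray(y)
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                    class_weight=class_weighting)
    forest.fit(X[genes], y)
    return ClassifierModel(
        selected_genes=genes, forest=forest,
        classes=[str(c) for c in forest.classes_],
        metadata={"n_trees": n_trees, "seed": seed,
                  "class_weighting": class_weighting})


def predict(model: ClassifierModel, X: pd.DataFrame) -> pd.DataFrame:
    """Per-label probabilities; genes missing from ``X`` are imputed as 0."""
    missing = [g for g in model.selected_genes if g not in X.columns]
    if missing:
        warnings.warn(f"genes missing from prediction data imputed as 0: {missing}",
                      UserWarning)
        X = X.copy()
        for g in missing:
            X[g] = 0.0
    probs = model.forest.predict_proba(X[model.selected_genes])
    return pd.DataFrame(probs, index=X.index, columns=model.classes)


def directionality_ratio_bulk(expression: pd.DataFrame, tcr_signature,
                              bystander_signature) -> pd.Series:
    """Per-patient ratio of TCR to bystander activation metagenes."""
    from .signaling import metagene

    num = metagene(expression, tcr_signature)
    den = metagene(expression, bystander_signature)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = num / den
    return ratio.where(den != 0).rename("tcr_to_bystander_ratio")
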