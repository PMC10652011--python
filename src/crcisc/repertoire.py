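"""TCR repertoire analysis: alignment identity, clonotypes, epitope annotation,
exclusivity and MAIT calling, and clonal diversity statistics.

Sequence comparisons use local amino-acid alignment under BLOSUM62 with gap-open
and gap-extension penalties of 4 (a gap of length L costs 4 + 4*(L-1)). Identity
between sequences is expressed as a fraction of a self-alignment score; which
self-score serves as the denominator differs by operation and follows the
analysis each implements:

* :func:`identity_fraction` — fraction of the *target's* self-score (used for
  MAIT identity to known reference sequences);
* :func:`call_exclusive` — fraction of the *tumor query's* self-score when
  scanning normal-adjacent sequences, with a strict 0.80 exclusivity threshold.

Clonotype-cluster distance is ``d(a, b) = min(self(a), self(b)) - score(a, b)``,
a symmetric, zero-on-identity form isolated in :func:`alignment_distance` so it
can be swapped if a different convention is preferred.
"""

from __future__ import annotations

import hashlib
import warnings
from functools import lru_cache

import numpy as np
import pandas as pd
import scipy.sparse
import scipy.sparse.csgraph
from Bio.Align import PairwiseAligner, substitution_matrices

from .resources import TCR_FAMILIES

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
GAP_OPEN = 4.0
GAP_EXTEND = 4.0
CLUSTER_CUTOFF = 15.0
EXCLUSIVE_IDENTITY = 0.80

_aligner = PairwiseAligner(
    mode="local",
    substitution_matrix=substitution_matrices.load("BLOSUM62"),
    open_gap_score=-GAP_OPEN,
    extend_gap_score=-GAP_EXTEND,
)


def _validate_seq(seq: str) -> str:
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - AA_ALPHABET
    if bad:
        raise ValueError(f"invalid amino-acid letters {sorted(bad)} in {seq!r}")
    return seq


@lru_cache(maxsize=200_000)
def local_align(a: str, b: str) -> float:
    """Best local alignment score of two CDR3 amino-acid sequences."""
    _validate_seq(a)
    _validate_seq(b)
    return float(_aligner.score(a, b))


def self_score(a: str) -> float:
    """Self alignment score (sum of BLOSUM62 diagonal entries for ``a``)."""
    return local_align(a, a)


def identity_fraction(query: str, target: str) -> float:
    """Local-alignment identity of ``query`` to ``target``.

    ``local_align(query, target) / local_align(target, target)``, clipped to
    [0, 1]; identical sequences score exactly 1.
    """
    return float(np.clip(local_align(query, target) / self_score(target), 0.0, 1.0))


def alignment_distance(a: str, b: str) -> float:
    """Symmetric alignment distance ``min(self(a), self(b)) - score(a, b)``.

    Zero for identical sequences, growing with dissimilarity; clonotypes with
    distance <= 15 are connected into clonotype clusters.
    """
    return min(self_score(a), self_score(b)) - local_align(a, b)


def mait_score(alpha_seqs, beta_seqs, known_pairs: pd.DataFrame) -> float:
    """Best alpha x beta identity product against known MAIT TCR pairs.

    For each known (alpha*, beta*) pair the identity of the cell's alpha chain
    to alpha* is multiplied by the identity of its beta chain to beta* (each a
    fraction of the known sequence's self-score); the maximum product over
    known pairs and over the cell's chains is returned. Requires at least one
    productive alpha and beta chain.
    """
    alphas = [s for s in alpha_seqs if isinstance(s, str) and s]
    betas = [s for s in beta_seqs if isinstance(s, str) and s]
    if not alphas or not betas:
        raise ValueError("cell must have at least one alpha and one beta chain")
    best = 0.0
    for _, pair in known_pairs.iterrows():
        fa = max(identity_fraction(a, pair["cdr3_alpha_aa"]) for a in alphas)
        fb = max(identity_fraction(b, pair["cdr3_beta_aa"]) for b in betas)
        best = max(best, fa * fb)
    return best


def mait_score_table(records: pd.DataFrame, known_pairs: pd.DataFrame) -> pd.Series:
    """Per-cell MAIT identity score; cells missing a chain are excluded."""
    scores = {}
    for cell, grp in records[records["productive"]].groupby("cell_id"):
        alphas = grp.loc[grp["locus"] == "TRA", "junction_aa"].tolist()
        betas = grp.loc[grp["locus"] == "TRB", "junction_aa"].tolist()
        if alphas and betas:
            scores[cell] = mait_score(alphas, betas, known_pairs)
    return pd.Series(scores, name="mait_score")


def call_exclusive(tumor_betas, normal_betas,
                   threshold: float = EXCLUSIVE_IDENTITY) -> pd.Series:
    """Flag tumor beta-chain CDR3s absent from the normal-adjacent repertoire.

    A tumor sequence is *exclusive* when its best identity against every normal
    beta chain — ``score(tumor, normal) / self(tumor)`` — is strictly below the
    threshold (0.80). An empty normal set makes every tumor TCR exclusive, with
    a warning.
    """
    tumor_betas = list(tumor_betas)
    normal_betas = list(dict.fromkeys(normal_betas))
    if not normal_betas:
        warnings.warn("empty normal repertoire: all tumor TCRs called exclusive",
                      UserWarning)
        return pd.Series(True, index=tumor_betas)
    out = {}
    for t in tumor_betas:
        denom = self_score(t)
        best = max(local_align(t, n) for n in normal_betas) / denom
        out[t] = bool(min(best, 1.0) < threshold)
    return pd.Series(out)


def define_clonotypes(records: pd.DataFrame) -> pd.Series:
    """Assign clonotype ids: cells sharing identical CDR3 nucleotide sequences
    on all their productive chains share a clonotype.

    Ids are stable across runs (hash of the sorted (locus, junction) tuples).
    Cells with a single recovered chain form single-chain clonotypes, flagged by
    an ``sc-`` id prefix.
    """
    prod = records[records["productive"]]
    ids = {}
    for cell, grp in prod.groupby("cell_id"):
        key = tuple(sorted(zip(grp["locus"], grp["junction"])))
        digest = hashlib.sha1(repr(key).encode()).hexdigest()[:12]
        prefix = "sc-" if len(key) < 2 else "ct-"
        ids[cell] = prefix + digest
    return pd.Series(ids, name="clonotype_id")


def clonotype_representatives(records: pd.DataFrame, clonotypes: pd.Series,
                              locus: str = "TRB") -> pd.Series:
    """Representative CDR3 aa per clonotype (preferred locus, alpha fallback)."""
    prod = records[records["productive"]].copy()
    prod["clonotype_id"] = prod["cell_id"].map(clonotypes)
    reps = {}
    for ct, grp in prod.dropna(subset=["clonotype_id"]).groupby("clonotype_id"):
        pref = grp.loc[grp["locus"] == locus, "junction_aa"]
        reps[ct] = pref.iloc[0] if len(pref) else grp["junction_aa"].iloc[0]
    return pd.Series(reps, name="cdr3_aa")


def cluster_clonotypes(representatives: pd.Series,
                       cutoff: float = CLUSTER_CUTOFF) -> pd.Series:
    """Group clonotypes into clusters by alignment distance <= cutoff.

    Clusters are connected components of the graph linking clonotypes whose
    representative sequences have :func:`alignment_distance` at most ``cutoff``
    (chained similarity joins transitively). Ids are ``cl-<n>`` numbered by
    first occurrence in sorted clonotype order, so they are invariant to record
    order.
    """
    cts = sorted(representatives.index)
    seqs = [representatives[c] for c in cts]
    n = len(cts)
    rows, cols = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if alignment_distance(seqs[i], seqs[j]) <= cutoff:
                rows.append(i)
                cols.append(j)
    graph = scipy.sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, comp = scipy.sparse.csgraph.connected_components(graph, directed=False)
    relabel, out = {}, {}
    for ct, c in zip(cts, comp):
        if c not in relabel:
            relabel[c] = len(relabel)
        out[ct] = f"cl-{relabel[c]}"
    return pd.Series(out, name="cluster_id").reindex(representatives.index)


def annotate_epitopes(representatives: pd.Series, reference: pd.DataFrame,
                      strategy: str = "most-frequent",
                      cutoff: float = CLUSTER_CUTOFF,
                      locus: str = "TRB",
                      exclusive_ids=None) -> pd.DataFrame:
    """Predict epitope / organism / family per clonotype from a reference table.

    Candidate hits are reference CDR3s of the same locus within alignment
    distance ``cutoff``; the most frequent (epitope, organism) among hits wins.
    A tie yields ``ambiguous``; no hit yields ``Unknown``. Clonotypes listed in
    ``exclusive_ids`` (e.g. from :func:`call_exclusive`) override to family
    ``exclusive``.
    """
    if strategy != "most-frequent":
        raise ValueError(f"unsupported strategy {strategy!r}")
    if reference.empty:
        raise ValueError("empty epitope reference")
    ref = reference[reference["locus"] == locus] if "locus" in reference else reference
    exclusive_ids = set(exclusive_ids or ())
    rows = []
    ref_seqs = ref["junction_aa"].tolist()
    for ct, seq in representatives.items():
        if ct in exclusive_ids:
            rows.append((ct, "none", "none", "exclusive"))
            continue
        hits = ref[[alignment_distance(seq, r) <= cutoff for r in ref_seqs]]
        if hits.empty:
            rows.append((ct, "Unknown", "Unknown", "Unknown"))
            continue
        counts = hits.groupby(["epitope", "organism"]).size().sort_values(
            ascending=False)
        if len(counts) > 1 and counts.iloc[0] == counts.iloc[1]:
            rows.append((ct, "ambiguous", "ambiguous", "ambiguous"))
            continue
        epitope, organism = counts.index[0]
        fam_counts = hits[(hits["epitope"] == epitope)
                          & (hits["organism"] == organism)]["family"]
        family = fam_counts.mode().iloc[0]
        if family not in TCR_FAMILIES:
            family = "unknown"
        rows.append((ct, epitope, organism, family))
    return pd.DataFrame(rows, columns=["clonotype_id", "epitope", "organism",
                                       "family"]).set_index("clonotype_id")


def clonal_expansion(clonotypes: pd.Series,
                     strata: pd.DataFrame | None = None) -> pd.DataFrame:
    """Cells per clonotype, optionally stratified by per-cell annotations.

    ``strata`` is indexed by cell id; stratified counts sum to the unstratified
    totals by construction.
    """
    counts = clonotypes.value_counts().rename("expansion").to_frame()
    counts.index.name = "clonotype_id"
    if strata is None:
        return counts
    joined = strata.reindex(clonotypes.index).assign(clonotype_id=clonotypes)
    table = joined.groupby(["clonotype_id", *strata.columns]).size().rename(
        "expansion").reset_index()
    return table


# ---------------------------------------------------------------------------
# diversity statistics (library implementations serve as oracles in the tests)

def _abundances(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0 or (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise ValueError("abundances must be non-negative integers")
    arr = arr[arr > 0]
    if arr.size == 0:
        raise ValueError("at least one abundance must be nonzero")
    return arr


def chao1(abundances) -> float:
    """Bias-corrected Chao1 richness: ``S_obs + F1*(F1-1) / (2*(F2+1))``."""
    arr = _abundances(abundances)
    s_obs = arr.size
    f1 = int((arr == 1).sum())
    f2 = int((arr == 2).sum())
    return float(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


def shannon_normalized(abundances) -> float:
    """Shannon entropy over observed categories divided by ln(S); 0 when S=1."""
    arr = _abundances(abundances)
    if arr.size == 1:
        return 0.0
    p = arr / arr.sum()
    h = float(-(p * np.log(p)).sum())
    return h / float(np.log(arr.size))


def heip_evenness(abundances) -> float:
    """Heip's evenness ``(e^H - 1) / (S - 1)``; 1 when S=1 by convention."""
    arr = _abundances(abundances)
    if arr.size == 1:
        return 1.0
    p = arr / arr.sum()
    h = float(-(p * np.log(p)).sum())
    return float((np.exp(h) - 1.0) / (arr.size - 1.0))
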