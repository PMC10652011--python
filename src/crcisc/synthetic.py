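"""Synthetic data generators emulating the statistical structure the pipeline
assumes, so every downstream stage is testable without any external download.

Three generators are provided:

* :func:`simulate_sc_expression` — single-cell log-normalized expression with
  block-correlated planted modules over the 39-gene universe and a bimodal IFNG
  marginal whose detection valley sits near 0.2;
* :func:`simulate_tcr_repertoire` — an AIRR-style rearrangement table with
  power-law clone sizes, planted epitope-family matches, planted tumor-exclusive
  CDR3s and exact MAIT alpha/beta pairs, together with the matching epitope
  reference table;
* :func:`simulate_bulk_cohort` — a patients x genes bulk expression matrix with
  planted ISC group structure on the module metagenes plus group-dependent
  exponential survival.

One global seed fans out into per-generator child seeds via
:func:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import repertoire as rep
from .preprocess import CellTable
from .resources import (GENE_UNIVERSE_39, TCR_FAMILIES, canonical_modules,
                        synthetic_mait_pairs)

AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: one deterministic codon per amino acid, so nt equality <=> aa equality
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


def _child_seed(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(stream + 1)[stream])


# ---------------------------------------------------------------------------
# single-cell expression


@dataclass
class PlantedModule:
    name: str
    genes: list[str]
    rho: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")


def _default_planted_modules() -> list[PlantedModule]:
    return [PlantedModule(name, genes, 0.8)
            for name, genes in canonical_modules("MSI").items()]


@dataclass
class ScSimConfig:
    """Configuration for the single-cell expression generator.

    ``planted_modules`` must be disjoint subsets of ``gene_universe``; genes in
    no module are simulated independently. The IFNG marginal is a two-component
    mixture (a near-zero detection component and an expressing component) with
    ``ifng_positive_fraction`` of cells above the valley, rank-coupled to IFNG's
    latent module factor so planted correlations survive the override.
    """

    n_patients: int = 8
    cells_per_patient: int = 250
    gene_universe: list[str] = field(default_factory=lambda: list(GENE_UNIVERSE_39))
    planted_modules: list[PlantedModule] = field(
        default_factory=_default_planted_modules)
    ifng_positive_fraction: float = 0.4
    noise_sd: float = 0.6
    subtype: str = "MSI"
    normal_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ifng_positive_fraction <= 1.0:
            raise ValueError("ifng_positive_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        seen: set[str] = set()
        for mod in self.planted_modules:
            genes = set(mod.genes)
            if genes - set(self.gene_universe):
                raise ValueError(f"module {mod.name} has genes outside the universe")
            if genes & seen:
                raise ValueError(
                    f"planted modules must be disjoint; overlap at {genes & seen}")
            seen |= genes


def _ifng_mixture(rng: np.random.Generator, n: int, positive_fraction: float
                  ) -> np.ndarray:
    """Bimodal IFNG marginal with the density valley near 0.2 log2-CPM."""
    positive = rng.random(n) < positive_fraction
    low = np.abs(rng.normal(0.0, 0.05, n))
    high = 0.45 + np.abs(rng.normal(0.75, 0.35, n))
    return np.where(positive, high, low)


def simulate_sc_expression(config: ScSimConfig) -> CellTable:
    """Generate a :class:`~crcisc.preprocess.CellTable` with planted structure.

    Within each planted module, gene values share a latent Gaussian factor so
    pairwise Spearman correlations approach the configured rho (a Gaussian
    copula with rank-preserving truncation at 0). Deterministic for a fixed
    seed.
    """
    rng = _child_seed(config.seed, 0)
    genes = list(config.gene_universe)
    n_cells = config.n_patients * config.cells_per_patient
    # latent correlation for a Gaussian copula targeting Spearman rho
    module_of = {g: m for m in config.planted_modules for g in m.genes}

    latent = rng.standard_normal((n_cells, len(genes)))
    factors = {m.name: rng.standard_normal(n_cells) for m in config.planted_modules}
    for j, g in enumerate(genes):
        mod = module_of.get(g)
        if mod is not None and mod.rho > 0:
            r = 2.0 * np.sin(np.pi * mod.rho / 6.0)  # Pearson for target Spearman
            w = np.sqrt(r)
            latent[:, j] = w * factors[mod.name] + np.sqrt(1 - r) * latent[:, j]

    base_mean = rng.uniform(0.8, 2.5, len(genes))
    expr = np.clip(base_mean + config.noise_sd * latent, 0.0, None)

    # IFNG marginal override, rank-coupled to its latent column
    if "IFNG" in genes:
        j = genes.index("IFNG")
        mixture = np.sort(
            _ifng_mixture(rng, n_cells, config.ifng_positive_fraction))
        order = np.argsort(latent[:, j], kind="stable")
        col = np.empty(n_cells)
        col[order] = mixture
        expr[:, j] = col

    cell_ids = [f"cell_{i:05d}" for i in range(n_cells)]
    patients = np.repeat(
        [f"P{p:02d}" for p in range(config.n_patients)], config.cells_per_patient)
    tissue = np.where(rng.random(n_cells) < config.normal_fraction,
                      "normal", "tumor")
    subpops = np.array(["Tcm", "Tem", "Tex", "Trm", "MAIT"])[
        rng.integers(0, 5, n_cells)]
    expression = pd.DataFrame(expr, index=cell_ids, columns=genes)
    metadata = pd.DataFrame({
        "patient_id": patients,
        "tissue": tissue,
        "subtype": config.subtype,
        "subpopulation": subpops,
    }, index=cell_ids)
    metadata["ifng_positive"] = (expression["IFNG"] > 0.2
                                 if "IFNG" in genes else False)
    return CellTable(expression, metadata)


# ---------------------------------------------------------------------------
# TCR repertoire


def _default_family_proportions() -> dict[str, float]:
    return {"viral": 0.45, "bacterial": 0.05, "self": 0.05, "shared": 0.05,
            "exclusive": 0.25, "unknown": 0.15}


@dataclass
class TcrSimConfig:
    n_clonotypes: int = 150
    expansion_exponent: float = 1.5
    family_proportions: dict[str, float] = field(
        default_factory=_default_family_proportions)
    n_mait_pairs: int = 5
    mutation_rate: float = 0.0
    n_reference_per_family: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.expansion_exponent <= 0:
            raise ValueError("expansion_exponent must be positive")
        if abs(sum(self.family_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("family_proportions must sum to 1")
        unknown_keys = set(self.family_proportions) - set(TCR_FAMILIES)
        if unknown_keys:
            raise ValueError(f"unknown families: {sorted(unknown_keys)}")


_ORGANISM = {"viral": "Cytomegalovirus", "bacterial": "Mycobacterium tuberculosis",
             "self": "Homo sapiens", "shared": "Homo sapiens (shared tumor)"}


def _random_cdr3(rng: np.random.Generator, length: int | None = None) -> str:
    length = length if length is not None else int(rng.integers(8, 13))
    return "C" + "".join(rng.choice(AA20, length)) + "F"


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = []
    for ch in seq:
        if rng.random() < rate:
            choices = [a for a in AA20 if a != ch]
            out.append(choices[int(rng.integers(0, len(choices)))])
        else:
            out.append(ch)
    return "".join(out)


def reverse_translate(aa: str) -> str:
    """Deterministic one-codon-per-residue nucleotide sequence for a CDR3."""
    return "".join(_CODON[ch] for ch in aa)


def _far_from(rng, refs: list[str], min_tries: int = 200) -> str:
    """Random CDR3 with < 80% identity (tumor-self-score normalized) to refs."""
    for _ in range(min_tries):
        cand = _random_cdr3(rng)
        if all(rep.local_align(cand, r) / rep.self_score(cand) < 0.75
               for r in refs):
            return cand
    raise RuntimeError("could not place a distant CDR3; reference too dense")


def simulate_tcr_repertoire(config: TcrSimConfig
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate an AIRR rearrangement table and the matching epitope reference.

    Clone sizes follow a discretized Pareto law with the configured tail
    exponent. Clonotypes of annotatable families carry beta CDR3s within
    ``mutation_rate`` per-residue substitutions of a reference entry; exclusive
    and unknown clonotypes are placed below 80% identity of every reference.
    Exclusive clonotypes occur only in tumor tissue; all other clonotypes also
    seed the normal-adjacent repertoire. The first ``n_mait_pairs`` cells carry
    exact known MAIT alpha/beta pairs (from the synthetic stand-in table).
    """
    rng = _child_seed(config.seed, 1)
    annotatable = [f for f in ("viral", "bacterial", "self", "shared")
                   if config.family_proportions.get(f, 0) > 0]
    reference_rows = []
    ref_seqs: dict[str, list[str]] = {}
    all_refs: list[str] = []
    for fam in annotatable:
        ref_seqs[fam] = []
        for i in range(config.n_reference_per_family):
            seq = _far_from(rng, all_refs) if all_refs else _random_cdr3(rng)
            ref_seqs[fam].append(seq)
            all_refs.append(seq)
            reference_rows.append(
                (seq, "TRB", f"{fam}_epitope_{i}", _ORGANISM[fam], fam))
    reference = pd.DataFrame(
        reference_rows,
        columns=["junction_aa", "locus", "epitope", "organism", "family"])

    families = rng.choice(list(config.family_proportions),
                          size=config.n_clonotypes,
                          p=list(config.family_proportions.values()))
    sizes = np.floor(rng.pareto(config.expansion_exponent,
                                config.n_clonotypes)).astype(int) + 1

    # first pass: sequences for non-exclusive clonotypes (these seed the
    # normal-adjacent repertoire), so exclusives can be placed far from ALL of
    # them, guaranteeing < 80% identity against everything normal
    betas: list[str | None] = [None] * config.n_clonotypes
    normal_pool: list[str] = list(all_refs)
    for ct_idx, fam in enumerate(families):
        if fam in ref_seqs:
            ref = ref_seqs[fam][int(rng.integers(0, len(ref_seqs[fam])))]
            betas[ct_idx] = _mutate(rng, ref, config.mutation_rate)
            normal_pool.append(betas[ct_idx])
        elif fam == "unknown":
            betas[ct_idx] = _far_from(rng, all_refs)
            normal_pool.append(betas[ct_idx])
    for ct_idx, fam in enumerate(families):
        if fam == "exclusive":
            betas[ct_idx] = _far_from(rng, normal_pool)

    records = []
    clonotype_meta = []
    cell_counter = 0
    for ct_idx, (fam, size) in enumerate(zip(families, sizes)):
        beta = betas[ct_idx]
        alpha = _random_cdr3(rng)
        clonotype_meta.append((f"planted_{ct_idx:04d}", fam, int(size)))
        dup = int(rng.integers(1, 10))
        for _ in range(int(size)):
            cell_id = f"tcell_{cell_counter:05d}"
            cell_counter += 1
            for locus, seq, v, j in (("TRA", alpha, "TRAV1-2", "TRAJ33"),
                                     ("TRB", beta, "TRBV20-1", "TRBJ2-7")):
                records.append({
                    "cell_id": cell_id, "locus": locus,
                    "junction": reverse_translate(seq), "junction_aa": seq,
                    "v_call": v, "j_call": j, "productive": True,
                    "duplicate_count": dup, "tissue": "tumor",
                    "planted_clonotype": f"planted_{ct_idx:04d}",
                    "planted_family": fam,
                })
        # non-exclusive clonotypes also seed the normal-adjacent repertoire
        if fam != "exclusive":
            cell_id = f"ncell_{ct_idx:05d}"
            for locus, seq, v, j in (("TRA", alpha, "TRAV1-2", "TRAJ33"),
                                     ("TRB", beta, "TRBV20-1", "TRBJ2-7")):
                records.append({
                    "cell_id": cell_id, "locus": locus,
                    "junction": reverse_translate(seq), "junction_aa": seq,
                    "v_call": v, "j_call": j, "productive": True,
                    "duplicate_count": 1, "tissue": "normal",
                    "planted_clonotype": f"planted_{ct_idx:04d}",
                    "planted_family": fam,
                })

    # MAIT cells are appended as dedicated cells carrying exact known pairs
    mait_pairs = synthetic_mait_pairs()
    for m in range(config.n_mait_pairs):
        pair = mait_pairs.iloc[m % len(mait_pairs)]
        cell_id = f"mait_{m:04d}"
        for locus, seq, v, j in ((
                "TRA", pair["cdr3_alpha_aa"], "TRAV1-2", "TRAJ33"), (
                "TRB", pair["cdr3_beta_aa"], "TRBV6-1", "TRBJ2-1")):
            records.append({
                "cell_id": cell_id, "locus": locus,
                "junction": reverse_translate(seq), "junction_aa": seq,
                "v_call": v, "j_call": j, "productive": True,
                "duplicate_count": 1, "tissue": "tumor",
                "planted_clonotype": f"mait_{m % len(mait_pairs):02d}",
                "planted_family": "mait",
            })
    table = pd.DataFrame(records)
    table.attrs["planted_clonotypes"] = pd.DataFrame(
        clonotype_meta, columns=["planted_clonotype", "family", "size"])
    return table, reference


# ---------------------------------------------------------------------------
# bulk cohort


def _msi_default_shifts() -> dict[str, dict[str, float]]:
    """Two MSI-like planted profiles mirroring the described ISC1a/1b biology:
    a stem-like-dominant cluster (with some immunosurveillance) vs a mixed
    inflammatory cluster led by tumor-reactive exhaustion."""
    return {
        "ISC1a-like": {"MSI_stem_like_progenitor": 3.0,
                       "MSI_long_term_immunosurveillance": 2.5,
                       "MSI_inflamed_follicular_like": 0.5,
                       "MSI_tumor_reactive_exhaustion": 0.5,
                       "MSI_memory_differentiation": 0.5},
        "ISC1b-like": {"MSI_tumor_reactive_exhaustion": 3.0,
                       "MSI_inflamed_follicular_like": 2.5,
                       "MSI_memory_differentiation": 2.5,
                       "MSI_long_term_immunosurveillance": 0.5},
    }


@dataclass
class BulkSimConfig:
    """Bulk cohort generator with planted ISC group structure.

    ``metagene_shift`` maps each group label to per-module mean shifts in units
    of ``noise_sd``; the shift is distributed over a module's genes with a
    group-specific +-50% ramp so that groups are also distinguishable by
    within-module rank patterns (as they are in real cohorts, where module
    genes respond with unequal magnitudes). Survival times are exponential with
    ``baseline_hazard * group_hazard_ratio[group]`` and censoring is applied
    independently with probability ``censor_rate``.
    """

    n_patients: int = 60
    group_labels: list[str] = field(
        default_factory=lambda: ["ISC1a-like", "ISC1b-like"])
    metagene_shift: dict[str, dict[str, float]] = field(
        default_factory=_msi_default_shifts)
    baseline_hazard: float = 0.03
    group_hazard_ratio: dict[str, float] | None = None
    censor_rate: float = 0.2
    noise_sd: float = 1.0
    subtype: str = "MSI"
    module_sets: dict[str, list[str]] | None = None
    baseline_range: tuple[float, float] = (4.5, 5.5)
    response_factor_range: tuple[float, float] = (-1.0, 3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.group_hazard_ratio is None:
            self.group_hazard_ratio = {g: 1.0 for g in self.group_labels}
        for g in self.group_labels:
            if g not in self.metagene_shift:
                raise ValueError(f"group {g!r} has no defined metagene shift")
            if g not in self.group_hazard_ratio:
                raise ValueError(f"group {g!r} has no hazard ratio")
            if self.group_hazard_ratio[g] <= 0:
                raise ValueError("hazard ratios must be positive")
        if self.module_sets is None:
            # simulate the full 39-gene universe: shifts may target one subtype's
            # modules, but distances downstream use all ten signatures
            self.module_sets = canonical_modules()
        for g, shifts in self.metagene_shift.items():
            undefined = set(shifts) - set(self.module_sets)
            if undefined:
                raise ValueError(f"shift on undefined modules for {g!r}: "
                                 f"{sorted(undefined)}")


def mss_default_bulk_config(n_patients: int = 150, seed: int = 0,
                            shift: float = 3.0) -> BulkSimConfig:
    """Five MSS-like planted groups with a graded overall module signal.

    Every group shifts all five MSS modules, with magnitude graded from the
    most inflamed (ISC2a-like, full ``shift``) to the most immune-silent
    (ISC3b-like, 20%% of it); each group's gene-level response pattern is
    group-specific, so groups differ both in overall metagene level (used for
    ISC naming) and in within-module rank patterns (used by the Spearman
    patient distances). Silent-side groups carry a higher hazard, matching the
    worse progression-free survival of immune-silent tumors.
    """
    modules = canonical_modules("MSS")
    order = ["ISC2a-like", "ISC2b-like", "ISC2c-like", "ISC3a-like",
             "ISC3b-like"]
    scales = [1.0, 0.8, 0.6, 0.4, 0.2]
    shifts = {g: {m: shift * s for m in modules}
              for g, s in zip(order, scales)}
    hazards = {"ISC2a-like": 1.0, "ISC2b-like": 1.0, "ISC2c-like": 1.0,
               "ISC3a-like": 2.5, "ISC3b-like": 2.5}
    return BulkSimConfig(
        n_patients=n_patients, group_labels=order, metagene_shift=shifts,
        group_hazard_ratio=hazards, subtype="MSS",
        module_sets=canonical_modules(), seed=seed)


def simulate_bulk_cohort(config: BulkSimConfig
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate bulk expression (patients x genes) and a survival table.

    Returns ``(expression, survival)`` where ``survival`` has columns
    ``patient_id``, ``time`` (months), ``event`` and ``group`` (the planted
    label, also stored in ``expression.attrs['planted_group']``).
    """
    rng = _child_seed(config.seed, 2)
    genes = sorted(set(g for gs in config.module_sets.values() for g in gs))
    groups = np.array([config.group_labels[i % len(config.group_labels)]
                       for i in range(config.n_patients)])
    # gene baselines and group response patterns are population-level biology:
    # they are keyed by gene/group/module names only, NOT by the seed, so two
    # cohorts drawn with different seeds share the same generative process and
    # a classifier trained on one transfers to the other
    brng = np.random.default_rng(zlib.crc32("|".join(genes).encode()))
    base_mean = brng.uniform(*config.baseline_range, len(genes))
    expr = base_mean + config.noise_sd * rng.standard_normal(
        (config.n_patients, len(genes)))

    gene_idx = {g: i for i, g in enumerate(genes)}
    for group in config.group_labels:
        shifts = config.metagene_shift[group]
        mask = groups == group
        for m, s in shifts.items():
            if s == 0:
                continue
            mod_genes = config.module_sets[m]
            # group-specific per-gene response factors, mean 1 over the module:
            # the module metagene shifts by s*noise_sd while the within-module
            # rank pattern distinguishes the groups
            grng = np.random.default_rng(zlib.crc32(f"{group}|{m}".encode()))
            factors = grng.uniform(*config.response_factor_range, len(mod_genes))
            factors += 1.0 - factors.mean()
            for g, f in zip(mod_genes, factors):
                expr[mask, gene_idx[g]] += s * config.noise_sd * f
    expr = np.clip(expr, 0.0, None)
    patients = [f"B{p:03d}" for p in range(config.n_patients)]
    expression = pd.DataFrame(expr, index=patients, columns=genes)
    expression.attrs["planted_group"] = pd.Series(groups, index=patients)

    hazards = np.array([config.baseline_hazard * config.group_hazard_ratio[g]
                        for g in groups])
    times = rng.exponential(1.0 / hazards)
    censored = rng.random(config.n_patients) < config.censor_rate
    obs_times = np.where(censored, times * rng.random(config.n_patients), times)
    survival = pd.DataFrame({
        "patient_id": patients,
        "time": obs_times,
        "event": ~censored,
        "group": groups,
    })
    return expression, survival
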