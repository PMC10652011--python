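"""End-to-end orchestration: simulate -> preprocess -> modules -> activation ->
TCR -> ISC -> survival, with a serialized config and a run manifest.

Every stage writes TSV outputs into the run directory; the manifest records
the package version, per-stage seeds and output file hashes so a rerun with
the same config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from . import repertoire as rep
from .activation import (directionality, quadrant_partition, reference_center,
                         score_activation)
from .preprocess import DEFAULT_BINARIZE_THRESHOLD
from .resources import canonical_modules, synthetic_mait_pairs
from .signaling import activation_map, discover_modules, metagene
from .stratify import compute_distance_matrices, isc_cluster, label_isc
from .survival import km_estimate, logrank_test
from .synthetic import (BulkSimConfig, ScSimConfig, TcrSimConfig,
                        simulate_bulk_cohort, simulate_sc_expression,
                        simulate_tcr_repertoire)

log = logging.getLogger("crcisc")


@dataclass
class RunConfig:
    """All pipeline thresholds with the canonical defaults.

    Defaults reproduce the analysis parameters verbatim: QC at >200 genes and
    >1000 reads, binarization at 0.2 log2-CPM, clonotype-cluster alignment
    cutoff 15, exclusivity identity 0.80, feature-importance threshold 0.001,
    non-directionality band 0.2.
    """

    seed: int = 0
    stages: list[str] = field(default_factory=lambda: [
        "simulate", "modules", "activation", "tcr", "isc", "survival"])
    qc_min_genes: int = 200
    qc_min_reads: int = 1000
    binarize_threshold: float = DEFAULT_BINARIZE_THRESHOLD
    alignment_cutoff: float = 15.0
    exclusive_threshold: float = 0.80
    importance_threshold: float = 0.001
    directionality_band: float = 0.2
    subtype: str = "MSI"
    n_module_clusters: int = 5
    sc_cells_per_patient: int = 250
    sc_n_patients: int = 8
    tcr_n_clonotypes: int = 120
    bulk_n_patients: int = 60

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the configured stages in dependency order.

    Returns the manifest dict (also written as ``manifest.json``). Raises a
    stage-naming error when a downstream stage misses its upstream output.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}}
    state: dict = {}

    if "simulate" in config.stages:
        log.info("stage=simulate seed=%d", config.seed)
        cells = simulate_sc_expression(ScSimConfig(
            n_patients=config.sc_n_patients,
            cells_per_patient=config.sc_cells_per_patient,
            subtype=config.subtype, seed=config.seed))
        records, reference = simulate_tcr_repertoire(TcrSimConfig(
            n_clonotypes=config.tcr_n_clonotypes, seed=config.seed))
        bulk, surv = simulate_bulk_cohort(BulkSimConfig(
            n_patients=config.bulk_n_patients, subtype=config.subtype,
            seed=config.seed))
        state.update(cells=cells, records=records, reference=reference,
                     bulk=bulk, surv=surv,
                     planted=bulk.attrs["planted_group"])
        cio.write_tsv(cells.expression, out / "sc_expression.tsv",
                      "simulate_sc_expression")
        cio.write_tsv(cells.metadata, out / "sc_metadata.tsv",
                      "simulate_sc_expression")
        cio.write_airr(records, out / "tcr_airr.tsv")
        cio.write_tsv(reference, out / "epitope_reference.tsv",
                      "simulate_tcr_repertoire", index=False)
        cio.write_tsv(bulk, out / "bulk_expression.tsv", "simulate_bulk_cohort")
        cio.write_tsv(surv, out / "survival.tsv", "simulate_bulk_cohort",
                      index=False)
        manifest["stages"]["simulate"] = {"seed": config.seed}

    if "modules" in config.stages:
        if "cells" not in state:
            raise RuntimeError("modules stage requires the simulate stage "
                               "(no cell table available)")
        cells = state["cells"]
        ifng_pos = cells.ifng_positive(config.binarize_threshold)
        pos = cells.subset(ifng_pos[ifng_pos].index)
        canon = canonical_modules(config.subtype)
        module_genes = sorted({g for gs in canon.values() for g in gs
                               if g in pos.expression.columns})
        discovered = discover_modules(pos.expression, module_genes,
                                      k=config.n_module_clusters)
        amap = activation_map(pos.expression, canon,
                              pos.metadata["subpopulation"],
                              config.binarize_threshold)
        state.update(ifng_pos=ifng_pos, modules=canon, discovered=discovered,
                     activation_map=amap)
        cio.write_gmt(discovered, out / "discovered_modules.gmt")
        cio.write_tsv(amap, out / "activation_map.tsv", "activation_map")
        manifest["stages"]["modules"] = {
            "n_ifng_positive": int(ifng_pos.sum()),
            "binarize_threshold": config.binarize_threshold}

    if "activation" in config.stages:
        if "cells" not in state:
            raise RuntimeError("activation stage requires the simulate stage")
        cells = state["cells"]
        rng = np.random.default_rng(config.seed + 17)
        genes = list(cells.expression.columns)
        tcr_centroid = pd.Series(rng.uniform(0, 3, len(genes)), index=genes)
        bys_centroid = pd.Series(rng.uniform(0, 3, len(genes)), index=genes)
        scores = score_activation(cells.expression, genes, tcr_centroid,
                                  bys_centroid)
        normal = scores.loc[cells.metadata["tissue"] == "normal"]
        center = reference_center(normal)
        labels, counts = quadrant_partition(scores, center)
        diff, klass = directionality(scores["r_tcr"], scores["r_bys"],
                                     config.directionality_band)
        state.update(activation_scores=scores.assign(quadrant=labels))
        cio.write_tsv(state["activation_scores"], out / "activation_scores.tsv",
                      "score_activation")
        cio.write_tsv(counts, out / "quadrant_counts.tsv", "quadrant_partition")
        manifest["stages"]["activation"] = {
            "directionality": diff, "classification": klass,
            "center": [center.center_tcr, center.center_bys]}

    if "tcr" in config.stages:
        if "records" not in state:
            raise RuntimeError("tcr stage requires the simulate stage")
        records, reference = state["records"], state["reference"]
        tumor = records[records["tissue"] == "tumor"]
        normal = records[records["tissue"] == "normal"]
        clonotypes = rep.define_clonotypes(tumor)
        reps = rep.clonotype_representatives(tumor, clonotypes)
        clusters = rep.cluster_clonotypes(reps, config.alignment_cutoff)
        normal_betas = normal.loc[(normal["locus"] == "TRB")
                                  & normal["productive"], "junction_aa"]
        exclusive = rep.call_exclusive(reps.unique(), normal_betas,
                                       config.exclusive_threshold)
        exclusive_ids = [ct for ct, seq in reps.items() if exclusive[seq]]
        annotations = rep.annotate_epitopes(
            reps, reference, cutoff=config.alignment_cutoff,
            exclusive_ids=exclusive_ids)
        expansion = rep.clonal_expansion(clonotypes)
        mait = rep.mait_score_table(tumor, synthetic_mait_pairs())
        abund = expansion["expansion"].to_numpy()
        diversity = pd.DataFrame([{
            "chao1": rep.chao1(abund),
            "shannon_normalized": rep.shannon_normalized(abund),
            "heip_evenness": rep.heip_evenness(abund),
        }])
        summary = annotations.join(clusters).join(expansion)
        state.update(clonotypes=clonotypes, annotations=summary, mait=mait)
        cio.write_tsv(summary, out / "clonotype_annotations.tsv",
                      "annotate_epitopes")
        cio.write_tsv(diversity, out / "tcr_diversity.tsv", "diversity",
                      index=False)
        cio.write_tsv(mait.to_frame(), out / "mait_scores.tsv", "mait_score")
        manifest["stages"]["tcr"] = {
            "n_clonotypes": int(clonotypes.nunique()),
            "n_exclusive": int(sum(exclusive[seq] for seq in reps))}

    if "isc" in config.stages:
        if "bulk" not in state:
            raise RuntimeError("isc stage requires the simulate stage")
        bulk = state["bulk"]
        # the patient manifold is defined by all ten module signatures;
        # naming uses the subtype's own five module metagenes
        dists = compute_distance_matrices(bulk, canonical_modules())
        n_groups = 2 if config.subtype.upper() == "MSI" else 5
        clusters, k = isc_cluster(dists.averaged, n_clusters=n_groups)
        subtype_modules = canonical_modules(config.subtype)
        metagenes = pd.DataFrame({m: metagene(bulk, gs)
                                  for m, gs in subtype_modules.items()})
        labels = label_isc(clusters, metagenes, config.subtype)
        state.update(isc_labels=labels)
        cio.write_tsv(dists.averaged, out / "patient_distances.tsv",
                      "compute_distance_matrices")
        cio.write_tsv(labels.to_frame(), out / "isc_labels.tsv", "label_isc")
        manifest["stages"]["isc"] = {"k": int(k)}

    if "survival" in config.stages:
        if "surv" not in state or "isc_labels" not in state:
            raise RuntimeError("survival stage requires the simulate and isc "
                               "stages")
        surv = state["surv"].set_index("patient_id")
        surv["isc_label"] = state["isc_labels"]
        groups = sorted(surv["isc_label"].dropna().unique())
        top = surv[surv["isc_label"] == groups[0]]
        rest = surv[surv["isc_label"] != groups[0]]
        curve = km_estimate(surv["time"], surv["event"])
        chi2, p = logrank_test(top["time"], top["event"],
                               rest["time"], rest["event"])
        cio.write_tsv(curve, out / "km_curve.tsv", "km_estimate", index=False)
        cio.write_tsv(pd.DataFrame([{"chi2": chi2, "p": p,
                                     "group_a": groups[0]}]),
                      out / "logrank.tsv", "logrank_test", index=False)
        manifest["stages"]["survival"] = {"logrank_chi2": chi2, "logrank_p": p}

    for f in sorted(out.glob("*.tsv")) + sorted(out.glob("*.gmt")):
        manifest["outputs"][f.name] = _hash_file(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest
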