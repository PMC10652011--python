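"""Curated gene panels and module definitions shipped with the package.

The tumor-reactive signaling universe consists of 39 genes: 21 genes marking
tumor-reactive CD8+ T cell exhaustion, 17 cytokine/TCR-signaling components and
transcription factors upstream of inhibitory-receptor genes, plus ``IFNG`` itself.
Ten co-expression modules (five per colorectal-cancer subtype, MSI and MSS) partition
subsets of this universe; they are shipped as a versioned GMT file whose description
field flags genes whose module membership was inferred rather than explicitly listed.
"""

from __future__ import annotations

from importlib import resources as _ilr

import pandas as pd

#: Genes marking tumor-reactive CD8+ T cell exhaustion.
EXHAUSTION_GENES = [
    "TIGIT", "PDCD1", "LAG3", "CTLA4", "HAVCR2", "ENTPD1", "TCF7", "TOX", "EOMES",
    "CXCL10", "CXCL9", "CXCL13", "CXCR5", "ICOS", "IL18R1", "IL15RA", "IL18RAP",
    "KLRG1", "KLRK1", "BCL6", "SLAMF6",
]

#: Cytokine / TCR signaling components and transcription factors upstream of
#: inhibitory-receptor genes.
SIGNALING_TF_GENES = [
    "IL2", "CD28", "TNF", "SMAD3", "SMAD4", "SMAD2", "NFATC1", "NFATC3", "NFATC2",
    "MAF", "STAT2", "STAT1", "JAK3", "PRDM1", "TBX21", "YY1", "NFIL3",
]

#: The 39-gene universe over which all tumor-reactive signaling modules are defined.
GENE_UNIVERSE_39 = sorted(set(EXHAUSTION_GENES) | set(SIGNALING_TF_GENES) | {"IFNG"})

#: 58-gene CD8+ T cell subtyping and immunoregulation panel.
CD8_PANEL_58 = [
    "AHR", "BATF", "BCL6", "BTLA", "CCL3", "CCL4", "CCL5", "CCR4", "CCR5", "CCR6",
    "CCR7", "CD27", "CD28", "CD4", "CD44", "PTPRC", "CD8A", "CD8B", "CTLA4", "CXCR3",
    "CXCR4", "CXCR5", "CXCR6", "ENTPD1", "EOMES", "FOXP3", "GATA3", "GZMA", "GZMB",
    "GZMK", "ICOS", "IFNG", "IKZF2", "IL10", "IL21R", "IL2RA", "IL2RB", "IL7R",
    "ITGAE", "KLF2", "KLRB1", "KLRG1", "LAG3", "MAF", "PDCD1", "PRF1", "REL", "SELL",
    "STAT1", "STAT3", "STAT4", "STAT6", "TBX21", "TIGIT", "TNF", "TNFRSF18",
    "TNFRSF9", "TOX",
]

MSI_MODULE_NAMES = [
    "MSI_stem_like_progenitor",
    "MSI_inflamed_follicular_like",
    "MSI_long_term_immunosurveillance",
    "MSI_tumor_reactive_exhaustion",
    "MSI_memory_differentiation",
]

MSS_MODULE_NAMES = [
    "MSS_long_term_immunosurveillance",
    "MSS_inflamed_follicular_like",
    "MSS_inflamed_memory_like",
    "MSS_ifng_associated_dysfunctional",
    "MSS_tolerogenic_cmaf",
]

#: Annotation families recognized for predicted TCR antigen specificities.
TCR_FAMILIES = ["viral", "bacterial", "self", "shared", "exclusive", "unknown"]


def _read_gmt_text(text: str) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for line in text.splitlines():
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def canonical_modules(subtype: str | None = None) -> dict[str, list[str]]:
    """Return the shipped tumor-reactive signaling modules.

    Parameters
    ----------
    subtype:
        ``"MSI"`` or ``"MSS"`` to restrict to the five modules of one colorectal
        cancer subtype; ``None`` returns all ten.
    """
    text = (_ilr.files("crcisc") / "data" / "tumor_reactive_modules.gmt").read_text()
    sets = _read_gmt_text(text)
    if subtype is None:
        return sets
    subtype = subtype.upper()
    if subtype not in ("MSI", "MSS"):
        raise ValueError(f"subtype must be 'MSI' or 'MSS', got {subtype!r}")
    return {k: v for k, v in sets.items() if k.startswith(subtype)}


def synthetic_mait_pairs() -> pd.DataFrame:
    """Synthetic stand-in table of paired MAIT alpha/beta CDR3 sequences.

    Columns: ``pair_id``, ``cdr3_alpha_aa``, ``cdr3_beta_aa``. These fabricated
    sequences emulate the role of a functionally validated riboflavin-reactive
    MAIT TCR pair list used for alpha x beta identity scoring.
    """
    path = _ilr.files("crcisc") / "data" / "synthetic_mait_pairs.tsv"
    with _ilr.as_file(path) as p:
        return pd.read_csv(p, sep="\t", comment="#").dropna().reset_index(drop=True)
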