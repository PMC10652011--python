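"""Stratify a bulk MSS-like cohort into ISC groups and compare survival.

Builds a 150-patient cohort with five planted groups, computes per-signature
Spearman patient distances over the ten module gene sets, clusters the
averaged dissimilarity, names the clusters ISC2a..ISC3b, and runs a log-rank
test between the inflamed (ISC2) and immune-silent (ISC3) sides.
"""

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from crcisc.resources import canonical_modules
from crcisc.signaling import metagene
from crcisc.stratify import (compute_distance_matrices, isc_cluster, label_isc)
from crcisc.survival import logrank_test
from crcisc.synthetic import mss_default_bulk_config, simulate_bulk_cohort

bulk, surv = simulate_bulk_cohort(mss_default_bulk_config(150, seed=1))
planted = bulk.attrs["planted_group"]

dists = compute_distance_matrices(bulk, canonical_modules())
clusters, k = isc_cluster(dists.averaged)
mss_modules = canonical_modules("MSS")
metagenes = pd.DataFrame({m: metagene(bulk, gs)
                          for m, gs in mss_modules.items()})
labels = label_isc(clusters, metagenes, "MSS")

print(f"chosen number of clusters: {k}")
print(f"recovery ARI vs planted groups: "
      f"{adjusted_rand_score(planted, clusters):.3f}")
print("ISC label counts:")
print(labels.value_counts().sort_index().to_string())

surv = surv.set_index("patient_id").assign(isc=labels)
inflamed = surv[surv["isc"].str.startswith("ISC2")]
silent = surv[surv["isc"].str.startswith("ISC3")]
chi2, p = logrank_test(inflamed["time"], inflamed["event"],
                       silent["time"], silent["event"])
print(f"log-rank ISC2 vs ISC3: chi2 = {chi2:.2f}, p = {p:.2e}")
# The generator plants a 2.5x hazard on the immune-silent side, so the
# inflamed ISC2 patients show significantly longer progression-free survival.
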