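"""Group statistics over a synthetic cohort's feature table.

Builds per-subject feature tables from planted edge differences between the
near and far conditions, runs the paired transfer-distance contrast and the
performance correlation, and prints the significant rows.
"""

import itertools

import numpy as np
import pandas as pd

import nirsnet as nn
from nirsnet.network import ROI_ORDER

rng = np.random.default_rng(3)
n = 31
edges = [f"wpco_{a}-{b}" for a, b in itertools.combinations(ROI_ORDER, 2)]

rows = []
perf = {}
for i in range(n):
    base = {e: 0.3 + 0.05 * rng.standard_normal() for e in edges}
    far = {e: v + 0.05 * rng.standard_normal() for e, v in base.items()}
    far["wpco_LOFA-ROFA"] += 0.08  # planted distance effect
    rows.append({"subject": f"S{i:02d}", "condition": "near", **base})
    rows.append({"subject": f"S{i:02d}", "condition": "far", **far})
    # performance tracks the far LIPFG-RIPFG edge plus noise
    perf[f"S{i:02d}"] = 40 + 100 * far["wpco_LIPFG-RIPFG"] + rng.standard_normal()

features = nn.build_feature_table(rows)
behavior = pd.DataFrame(
    {
        "subject_id": sorted(perf),
        "prior_score": rng.standard_normal(n),
        "performance_near": rng.standard_normal(n),
        "performance_far": [perf[s] for s in sorted(perf)],
    }
)

dist = nn.contrast_report(features, nn.ContrastDesign(kind="distance", feature_set="wpco"))
sig = dist[dist["p"] < 0.05].sort_values("p")
print("transfer-distance contrast (paired t, near vs far), p < 0.05:")
print(sig[["feature", "estimate", "stat", "df", "p", "q"]].round(4).to_string(index=False))

corr = nn.contrast_report(
    features, nn.ContrastDesign(kind="performance", feature_set="wpco"), behavior
)
top = corr.sort_values("p").head(3)
print("\nperformance correlation (Pearson r), strongest associations:")
print(top[["feature", "estimate", "df", "p", "q"]].round(4).to_string(index=False))

print("\nThe planted LOFA-ROFA shift is recovered by the paired contrast "
      "(negative estimate: near minus far), and the LIPFG-RIPFG edge "
      "correlates with performance as constructed. q is the "
      "Benjamini-Hochberg adjusted p across the 45 edges.")
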