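"""Compare normalization methods on a simulated screen.

Applies counts-per-million, median-of-ratios and replicate-based RUV to the
same raw counts and prints the replicate agreement each one achieves:
median per-prey coefficient of variation (lower is better) and the median
pairwise Pearson correlation of non-selected samples.
"""

import numpy as np

from y2hscreen import ScenarioConfig, simulate_experiment
from y2hscreen.normalization import (
    build_report,
    normalize_library_size,
    normalize_median_of_ratios,
    normalize_ruvs,
)

dataset = simulate_experiment(
    ScenarioConfig(n_preys=1_500, n_baits=2, n_replicates=3,
                   m0=1e7, target_population=2e8, depth=5e5),
    seed=3,
)
raw = dataset.counts

methods = {
    "raw": raw,
    "library_size": normalize_library_size(raw),
    "median_of_ratios": normalize_median_of_ratios(raw),
    "ruvs": normalize_ruvs(raw, k=1),
}
report = build_report(methods)

print(f"{'method':18s} {'median CV':>10s} {'median Pearson (non-sel)':>26s}")
for name in methods:
    cv = report.cv.query("method == @name")["cv"].median()
    r = report.pearson.query(
        "method == @name and condition == 'non_selected'"
    )["r"].median()
    print(f"{name:18s} {cv:10.3f} {r:26.3f}")

print("\npaired Wilcoxon signed-rank p-values between CV distributions:")
print(report.cv_wilcoxon.to_string(index=False, float_format="%.3g"))
print("\nSize-factor methods reduce between-replicate CV relative to raw"
      "\ncounts; tiny p-values mean the CV distributions differ.")
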