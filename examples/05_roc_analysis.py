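"""Group comparison and ROC analysis of the kinetic markers.

Simulates the default cohort, fits every lesion, and prints the
summary table: group mean +/- SD, Mann-Whitney p, AUC with DeLong 95%
CI and the Youden operating threshold per marker.
"""

import pandas as pd

from dcekinetics import (
    compare_auc_delong,
    fit_cohort,
    simulate_cohort,
    summarize_cohort,
    table2_cohort_spec,
)
from dcekinetics.stats import _marker_values

records = simulate_cohort(table2_cohort_spec(noise_sigma=0.01, seed=0))
fits = fit_cohort(records)
fitted = [r.with_fit(f) for r, f in zip(records, fits)]

summary = summarize_cohort(fitted, ("IDC", "benign"))
with pd.option_context("display.width", 140, "display.precision", 3):
    print(summary[["marker", "mean_IDC", "mean_benign", "p_value",
                   "auc", "auc_ci_low", "auc_ci_high", "threshold",
                   "sensitivity", "specificity"]])

# paired AUC comparison: fitted b vs the delayed-phase BI-RADS ratio
labels = [r.group for r in fitted]
b = [_marker_values(r, "b") for r in fitted]
delayed = [_marker_values(r, "delayed_rate") for r in fitted]
p = compare_auc_delong(b, delayed, labels, "IDC",
                       direction_a="smaller", direction_b="larger")
print(f"\nPaired DeLong test, fitted b vs delayed-phase rate: p = {p:.3g}")
print("Small p-values for b and c mirror the published finding that "
      "malignant lesions enhance earlier and more steeply; d on the "
      "1e-4 scale separates washout from persistent enhancement.")
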