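"""Simulate the full synthetic cohort and write it as CSV.

Draws 116 invasive-ductal-carcinoma and 38 benign lesions from the
published per-group parameter distributions, adds 2% curve noise, and
writes the curves in the pipeline's interchange format.
"""

import numpy as np

from dcekinetics import simulate_cohort, table2_cohort_spec, write_curves

spec = table2_cohort_spec(seed=0)
records = simulate_cohort(spec)
write_curves(records, "cohort_curves.csv")

for group in ("IDC", "benign"):
    bs = [r.true_params.b for r in records if r.group == group]
    print(f"{group}: n={len(bs)}, generating b mean "
          f"{np.mean(bs):.1f} +/- {np.std(bs, ddof=1):.1f} s")
print("\nWrote cohort_curves.csv (one row per lesion-phase). The group "
      "b means echo the published 19.6 vs 31.5 s: malignant lesions "
      "reach their maximum enhancement slope earlier.")
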