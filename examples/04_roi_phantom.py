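"""ROI extraction from a phase-image phantom via the DPS map.

Builds a single-slice 7-phase phantom with a washout lesion, locates
the lesion on the dynamic-phase-subtraction (early-minus-late) map,
places a circular ROI there and recovers the kinetic curve.
"""

import numpy as np

from dcekinetics import (
    RoiSpec,
    SigmoidParams,
    compute_dps_map,
    extract_roi_curve,
    simulate_phase_series,
)

lesion = SigmoidParams(a=1.5, b=19.6, c=0.3, d=-20e-4)  # strong washout
series = simulate_phase_series(lesion, center_mm=(16.0, 16.0), radius_mm=5.0)

dps = compute_dps_map(series)  # post-contrast phase 2 minus phase 6
bright = dps > 0.5 * dps.max()
iy, ix = (np.mean(np.nonzero(bright), axis=1))
center = (float((iy + 0.5) * series.voxel_size[0]),
          float((ix + 0.5) * series.voxel_size[1]))
print(f"bright DPS blob centered at {center} mm "
      f"(lesion center was (16, 16) mm)")

roi = RoiSpec(center_mm=center, radius_mm=2.0)  # pi*r^2 = 12.6 mm^2 >= 5
curve = extract_roi_curve(series, roi)
print("ROI mean signal per phase:", np.round(curve.si_array, 4))
print("\nThe washout lesion is bright on the early-minus-late map, and "
      "the ROI mean reproduces the generating kinetic curve exactly in "
      "this noiseless phantom.")
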