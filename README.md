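# dcekinetics

Sigmoid-model analysis of breast dynamic contrast-enhanced MRI
(DCE-MRI) kinetic curves: a forward enhancement model, a bounded
nonlinear least-squares fitter, the BI-RADS enhancement ratios,
circular-ROI curve extraction from phase images, and a Mann-Whitney /
ROC statistical layer — exercised end to end on seeded synthetic
lesion cohorts.

## The problem

Breast DCE-MRI acquires a T1-weighted volume before contrast injection
and then every minute from 30 s after it (seven phases in total).  The
mean signal intensity of a lesion ROI over these phases — the kinetic
curve — carries diagnostic information: invasive ductal carcinoma
(IDC) enhances earlier and more steeply and washes out in the delayed
phase, while benign masses enhance slowly and persistently.  The
kinetic curve is modelled here as a logistic rise with a linear late
drift,

    SI(t) = (a + d·t) / (1 + exp(−c·(t − b))) + SI₀

with `a` the plateau signal change (relative to the pre-contrast
baseline SI₀), `b` the time of maximum slope in seconds after
injection start, `c` the early-phase steepness (1/s), and `d` the
late-phase slope (washout when negative; reported on a ×10⁻⁴ scale).
The model parameters, fitted per lesion by least squares, are compared
between groups with the Mann-Whitney U test and evaluated as
diagnostic markers by ROC analysis (AUC with DeLong confidence
intervals, Youden operating thresholds, paired AUC comparisons),
alongside the two classical BI-RADS ratios SI_ph1/SI_pre and
SI_ph2/SI_ph6.

No patient data ship with the package.  The synthetic-cohort module
draws per-lesion parameters from the published group summaries
(IDC, n=116: a 1.5±0.4, b 19.6±8.2 s, c 0.3±0.3 /s, d −3.7±9.6 ×10⁻⁴/s;
benign, n=38: a 1.4±0.8, b 31.5±13.5 s, c 0.1±0.1 /s, d 2.2±19.9 ×10⁻⁴/s;
plus the luminal A-like vs other-IDC subtype split) as independent
truncated normals, simulates noisy curves, and small phase-image
phantoms for the ROI workflow.  See `docs/methods.md` for the model,
the estimator design and the generator's assumptions.

## A worked example

```python
import numpy as np
from dcekinetics import SigmoidParams, simulate_curve, fit_sigmoid

rng = np.random.default_rng(0)
truth = SigmoidParams(a=1.5, b=19.6, c=0.3, d=-3.7e-4)   # IDC group means
curve = simulate_curve(truth, noise_sigma=0.02, rng=rng)  # 2% noise
res = fit_sigmoid(curve)
print(res.params)
```

prints

```
SigmoidParams(a=1.486, b=19.75, c=0.300, d=-2.48e-04, si0=1.0)
```

— the plateau `a` and the time-to-maximum-slope `b` are recovered
within a few percent at 2% curve noise; the late slope `d` is the
noisiest quantity (it rests on small late-phase differences).  The
`examples/` directory holds one short script per capability (forward
model, single-curve fit, cohort simulation, ROI phantom, ROC analysis,
full pipeline); each prints what it computes and what the numbers mean.
An equivalent thin CLI exists: `dcekinetics full --seed 0 --out dce_run`.

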