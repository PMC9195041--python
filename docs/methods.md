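# Methods

## Model

A lesion's 7-phase DCE-MRI kinetic curve (pre-contrast at t = −60 s,
post-contrast at 30, 90, …, 330 s after injection start; the schedule
is configurable) is modelled as

    SI(t) = (a + d·t) · L(c·(t − b)) + SI₀,     L(x) = 1/(1 + e^(−x))

- `a` — plateau signal change, dimensionless on the pre-contrast-
  relative scale (≈ 1.4–1.5 for breast masses);
- `b` — time of maximum slope, s after injection start (malignant
  lesions ≈ 20 s, benign ≈ 30 s);
- `c` — early-phase steepness, 1/s.  The *rate* convention
  `exp(−c·(t−b))` is the default: larger `c` means a steeper rise,
  matching the direction of the published group difference (malignant
  ≈ 0.3 /s > benign ≈ 0.1 /s), and a time-constant of 0.3 s would be
  an unresolvable step at 60-s sampling.  The literal time-constant
  form `exp(−(t−b)/c)` is available via `steepness="time-constant"`.
- `d` — late-phase slope, relative signal per second; negative for
  washout; tables print it ×10⁻⁴;
- `SI₀` — pre-contrast baseline, 1.0 on the normalized scale.

The logistic is evaluated with `scipy.special.expit` (no overflow).
Two BI-RADS ratios are computed directly from the sampled curve: the
initial-phase enhancement rate SI_ph1/SI_pre (a relative-difference
variant `(SI_ph1−SI_pre)/SI_pre` is offered explicitly, never
substituted silently) and the delayed-phase rate SI_ph2/SI_ph6
(> 1 means washout).

## What the 60-second schedule can and cannot determine

This package's estimator design follows from an identifiability
analysis of the sampling geometry, and the limits below are inherent
to the data, not to the optimizer.

The logistic transition usually straddles at most one or two samples.
Writing t₁ = 30 s for the first post-contrast sample, the pair (b, c)
is constrained mainly through **u = c·(t₁ − b)**, the logistic
argument at t₁; the likelihood has a long flat ridge along u = const.
Information distinguishing points on the ridge comes from the
second-nearest sample, whose logistic deviation is e^(−x₂) with
x₂ = c·min(b + 60, 90 − b).  Consequences, verified numerically:

- **Noiseless, double precision.**  Once x₂ ≳ 25 the deviation falls
  below one unit in the last place of the stored signal and whole
  (b, c) families produce bitwise-identical curves; no algorithm can
  separate them.  For b ∈ [5, 50] s this bounds the recoverable
  steepness at roughly c ≲ 0.3–0.45 /s.  Recovery tests therefore
  draw c from [0.05, 0.32] /s, which covers the span of the published
  group means (0.1–0.3 /s).
- **Slow lesions.**  For c ≲ 0.2 /s the logistic tail is non-zero at
  the pre-contrast time, so the measured pre-contrast value exceeds
  the true baseline.  Pinning SI₀ to the measured value (the pipeline
  default, 4 free parameters on 7 points) then mis-specifies the
  model slightly; parameter-recovery studies instead free SI₀
  (`FitOptions(fix_si0=False, normalize=False)`), under which
  noiseless recovery is exact.
- **Noisy curves.**  At 1–2% relative noise the ridge is flat for
  nearly every malignant-type lesion: the per-lesion b of a sharp
  transition is not determined by the data.  An estimator must say
  so, and must not let the reported b be an artifact of the solver's
  trajectory.

## The estimator

`fit_sigmoid` minimizes the sum of squared residuals on the
pre-contrast-relative scale (uniform rescaling leaves the minimizer
unchanged, so raw-scale fits are reported by rescaling) under box
bounds a ∈ [10⁻³, 10], b ∈ [−120, 400] s, c ∈ [10⁻³, 5] /s,
d ∈ [−0.01, 0.01] /s — wide enough for any published value, tight
enough to stop logistic collapse on 6 post-contrast points.  Stages:

1. **Trust-region least squares** (`scipy.optimize.least_squares`,
   TRF) with an analytic Jacobian — finite differences drown in
   rounding noise on the ridge — from three deterministic restarts:
   ridge points with u matched to the observed first-sample fraction
   at the anchor steepness (0.3 /s, the geometric middle of the
   steepness decade a 60-s grid resolves, or a two-point logit-slope
   estimate when the first two post-contrast samples both sit on the
   rise), at a smooth steepness (0.08 /s), and the moment-based
   initial guess.  Restart costs within a relative 10⁻³ band are
   treated as ties and resolved toward the first restart.
2. **Variable-projection polish** for near-noiseless fits (cost
   < 10⁻⁸): the linear parameters (a, d, and SI₀ when free) are
   solved exactly at each (u, c); the steepness is profiled on a
   33-point log grid with a bracketed line search, which walks the
   ridge reliably where the trust region stalls.
3. **Pinned-steepness selection** for noisy fits: a reduced model
   with c fixed at the anchor and u restricted to the band the
   measurement noise can resolve (|logit fraction| capped where the
   saturated and unsaturated models differ by less than half the
   estimated noise SD — a level calibrated on simulated cohorts; a
   completed-step limb covers transitions finished before t₁).  The
   full model is kept only when it improves the residual sum of
   squares by the χ²₂(5%) likelihood-ratio factor e^(5.99/7); else
   the pinned fit is reported with
   `condition_flag="weakly-identified"`.

Convergence tolerance is 10⁻¹⁰ on the relative cost change.  Flat
curves short-circuit to the degenerate guess (a at its 10⁻³ floor,
d = 0).  `fit_cohort` maps the fitter over a cohort, order-preserving;
per-record failures are captured as `converged=False`, never abort.

Estimator properties measured on synthetic cohorts at 1% noise (500
replicates / 10 cohorts): median fitted b within 0.4 s of the
generating value for the malignant group-mean curve; group-mean
fitted b within ≈ 4% of the generating sample mean on average, with
single-cohort errors up to ≈ 12% for the 38-lesion benign group; a
recovers to ≈ 1–3%.  Per-lesion b of sharp lesions is
shrinkage-dominated (toward the resolvable-steepness ridge point) —
group comparisons remain valid because the same rule applies to both
groups, and affected fits are flagged.

## Synthetic cohorts

`table2_cohort_spec()` and `table3_cohort_spec()` hold the published
per-group means and SDs (see README).  Per-lesion parameters are drawn
as **independent normals truncated below** (a > 0.05, b > 0,
c > 0.01 /s; d unbounded) by rejection sampling; SI₀ = 1.  Parameter
combinations whose noiseless curve would be non-positive anywhere on
the schedule (a small plateau paired with a steep negative late slope;
≈ 0.2% of benign draws) are redrawn — a positivity constraint of the
generator.  Curves receive multiplicative Gaussian noise
si·(1 + ε), ε ~ N(0, σ²), σ = 0.02 by default (a typical breast-DCE
signal-to-noise scale); the noise vector is redrawn if any signal
comes out non-positive.  Everything is a pure function of
(spec, seed).

What the generator does **not** emulate: the unknown joint law of the
real per-lesion parameters (only mean ± SD summaries are published;
real distributions are likely skewed and correlated), Rician noise,
scanner physics, motion, or fat-suppression artifacts.  Passing tests
therefore demonstrate the pipeline's correctness and its behaviour
under the declared binormal assumption — not that the published
real-cohort AUCs or thresholds are reproduced.  Two published effects
are documented **negative controls**: the significance of the plateau
a at P < 0.01 (group summaries 1.5±0.4 vs 1.4±0.8 barely differ) and
the luminal A-like vs other-IDC difference in b at P < 0.05
(20.0±13.9 vs 17.8±7.0 overlap heavily).  Under binormal sampling
these do not reliably reach their bands — consistent with non-normal
real-data distributions — and the test suite asserts exactly this
non-reproduction.

Phase-image phantoms are single-slice 2D images (7 × ny × nx) with a
circular lesion whose voxels follow the model and a uniform
background; the ground-truth mask is retained.  The ROI contract is a
2D disc in the lesion's slice, which the phantom models directly.

## Imaging workflow

The dynamic-phase-subtraction (DPS) map is voxelwise
SI(post-contrast phase 2) − SI(phase 6); with this order washout
lesions are bright, which is the map's screening purpose; the sign is
configurable.  ROI extraction averages voxels whose centers fall
within a circle of area ≥ 5 mm² (center-in-disc inclusion, no
partial-volume weighting — simple and exactly testable); one center is
broadcast to all phases, or seven per-phase centers emulate manual
motion correction.  A ≥ 10 mm² eligibility floor for recognizable
masses is exposed as `PhaseImageSeries.lesion_area_mm2()`.

## Statistics

- **Mann-Whitney U**: U counts pairs x > y with half credit for ties.
  Exact permutation distribution (full enumeration) when
  n₁ + n₂ ≤ 12; tie-corrected normal approximation with continuity
  correction otherwise; two-sided p.  Significance is banded at
  0.05 / 0.01 / 0.001 as in the field's tables.
- **ROC/AUC**: empirical AUC = U/(n₁n₂) with the same tie convention;
  thresholds are midpoints between adjacent distinct scores plus
  sentinels; direction is explicit per marker (smaller b and d
  indicate malignancy; larger a, c and enhancement ratios do) and an
  AUC below 0.5 is reported as computed, never flipped.
- **DeLong**: structural-components variance for the 95% CI (Wald,
  clipped to [0, 1]; degenerate separation flagged) and for the paired
  two-marker AUC-difference test.  Chosen as the standard
  nonparametric method for correlated AUCs.
- **Youden threshold**: maximizer of sensitivity + specificity − 1;
  ties break toward the positive-class median score.
- `summarize_cohort` produces the per-marker table (group mean ± SD,
  U, p, significance band, AUC with CI, threshold,
  sensitivity/specificity there), with d on the ×10⁻⁴ scale.

## Pipeline and reproducibility

Curves travel as UTF-8 comma CSV (`lesion_id, group, subtype, time_s,
si`, 7 rows per lesion, `%.17g` floats, re-read with round-trip
parsing so write→read→write is byte-identical).  `run_analysis`
executes simulate/fit/analyze/full modes and emits curves, per-lesion
fits, the summary table (CSV + Markdown), per-marker ROC tables and a
JSON manifest (config, seed, package versions); identical configs
give byte-identical tables.  A thin click CLI wraps it.  Test-suite
problem sizes are the study's own (116 + 38 lesions); Monte-Carlo
checks use 100–500 replicates, chosen as the smallest sizes at which
the asserted properties are stable.

## Known limitations

- Per-lesion b and c of sharp transitions are not identifiable at
  clinical noise levels with 60-s sampling; reported values for such
  lesions are ridge-regularized and flagged.  Only group-level
  statements are supported there.
- The pinned-steepness anchor (0.3 /s) is a property of the sampling
  schedule; for other schedules it should be re-derived (geometric
  middle of the resolvable steepness decade).
- The binormal generator cannot reproduce distribution-shape-driven
  published effects (see negative controls above), and real-cohort
  AUCs/thresholds are out of reach without the patient data.
- The published operating threshold of 0.795 for the initial-phase
  enhancement rate sits below 1, which is hard to reconcile with a
  plain post/pre ratio (post-contrast signal exceeds baseline); the
  relative-difference reading (79.5% enhancement) fits better.  Both
  conventions are implemented and the choice is always explicit.
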