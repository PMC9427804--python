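# Methods

## The measurement and its models

After a blood-collection tube is stirred (an upside-down rotation that
drives the tube's air bubble through the blood at ~1000 1/s shear,
dispersing all aggregates), isolated erythrocytes re-aggregate and the
backscattered-light intensity decays. `eakit` models that decay three
ways:

1. **First-order ("mono-exponential") kinetics** — the aggregation event
   itself is rate-limiting, so the isolated-cell signal follows
   `I(t) = A0·e^(−kt)`. The fitted statistic is the half-life
   `EAK5s = ln 2 / k` computed on the first 5 s of the recording.
2. **Second-order kinetics** — doublet formation limited by the
   concentration of isolated cells (`d[B]/dt = k[A]²`), giving
   `1/I(t) = kt + 1/A0`, fitted by OLS on the inverse-intensity scale.
3. **Bi-exponential decomposition** — over ~20 s the syllectogram is a
   fast (rouleaux) plus a slow (3-D aggregation) exponential above a
   baseline: `I(t) = I_f·e^(−t/τ_f) + I_s·e^(−t/τ_s) + I_0`.

Assumptions: backscattered intensity is proportional to the concentration
of isolated erythrocytes (no calibration layer; absolute units are
meaningless and every statistic is scale-invariant by construction), and
the first-order description holds only for the early phase, which is why
the 5 s window is the default analysis segment. Two rate conventions
coexist deliberately: rate constants `k` in 1/s for the first- and
second-order models, time constants `τ` in seconds for the bi-exponential
model. They are separate, typed fields, never a bare "k".

## Fitting choices

* **Mono-exponential fit**: residuals minimised on the intensity scale
  with `scipy.optimize.least_squares` (positivity bounds, relative
  parameter tolerance 1e-10, iteration cap 200; non-convergence is
  reported on the result, never swallowed). Starting values come from the
  log-linear regression of `ln I` on `t` — deterministic and
  derivative-free. A log-linear slope ≥ 0 (within round-off) raises
  `NonDecayingSignalError`: a flat or rising signal has no aggregation
  kinetics to quantify.
* **No offset term by default.** The first-order model has none, and an
  offset is not identifiable from a 5 s window when the decay is slow.
  `fit_mono_exp(..., with_offset=True)` exists for exploration.
* **r²** is `1 − SS_res/SS_tot` on the scale actually fitted (intensity
  for the exponential models, `1/I` for the second-order model). The two
  scales are compared directly when discriminating models; that mirrors
  how fit quality is reported in this field.
* **Segment selection** fits 1.5/3/5/10 s windows and keeps the maximal
  r²; ties within 1e-4 resolve to the *shortest* window, since the early
  phase is the one the first-order model actually describes.
* **Bi-exponential initialization** is classical curve peeling: baseline
  from the mean of the final 5% of samples, slow component from a
  log-linear fit of the baseline-subtracted last third, fast component
  from the stripped first 3 s. With a slow time constant comparable to
  the recording length the tail has not reached baseline, so the peel is
  biased — it is only a start point, and it is retained on the result
  (`init_params`) for audit. The refinement fits all five constants;
  amplitudes are left unbounded so a sign flip is detectable, and a
  negative amplitude triggers a refit with non-negativity bounds
  (`clamped=True`). A time-constant separation below 2x, or a component
  whose amplitude collapses to nothing, raises
  `PoorlyIdentifiableWarning`.
* **Segment boundary** is closed: `extract_segment(s, 5)` keeps `t ≤ 5`,
  so a 5 s recording at 100 Hz contributes 501 points.

## What the simulator emulates — and what it does not

The generator stands in for the device and the clinical cohorts, since no
raw recordings are publicly deposited.

* **Noise**: additive Gaussian, default sd 0.5% of the initial intensity.
  No photodiode noise model is published; this scale was chosen once
  because the closed generator→fitter loop then shows a repeat CV of the
  fitted half-life near the ~2.3–2.6% observed on real tubes. A
  proportional-noise variant exists. Samples pushed non-positive are
  clipped to a tiny floor (logged; a warning fires if >1% of samples
  clip).
* **Subjects**: each repeat measurement draws its half-life from
  `Normal(EAK5s_true, intra_cv·EAK5s_true)` with `intra_cv = 0.026` by
  default, then generates a 5 s, 100 Hz recording. The sampling rate is a
  free configuration parameter (no rate is published for the device);
  100 Hz is a realistic photodiode acquisition rate.
* **Cohorts**: subject-level half-lives are Normal with the group's mean
  and SD (healthy 2.51 ± 0.38 s; cardiology 1.73 ± 0.34; ACS 1.70 ± 0.17;
  non-ACS 1.76 ± 0.44), truncated below at 0.2 s to exclude non-physical
  draws. Repeats are spread evenly over the hour after the draw.
* **Hematocrit pairs**: hematocrit uniform on [23.6, 55.3]%; the
  half-life is `r·z_hct + sqrt(1−r²)·ε` on standardized scales, which
  fixes the *population* correlation exactly regardless of marginals.
* **Shear rate**: mean bubble velocity `2·stroke·frequency` divided by
  the bubble-to-wall gap `(D_tube − D_bubble)/2`. The default geometry
  (13 mm tube, 12.76 mm bubble, 60 mm stroke, 1 Hz) is a declared
  convention producing an order-10³ 1/s estimate; the published figure is
  itself an order-of-magnitude estimate read from photographs, so this
  number is a consistency check, not a fluid-dynamics result.

What the simulator does **not** reproduce: optical artifacts (tube wall
reflections, LED drift), the disaggregation phase before t = 0, hematocrit
effects on the decay shape, non-Gaussian outliers from handling, or any
age/sex structure. Passing tests therefore demonstrate that the
*estimators* are unbiased and calibrated under the stated generative
model, not that the device behaves this way on real blood.

## Statistics

"Student's t test" means the pooled-variance two-tailed test, which is
the convention in the clinical tables this package mirrors; Welch is
available (`variant="welch"`), and when group SDs differ by more than 2x
(with at least 5 per group) the pooled path suggests it in a warning
rather than switching silently. Summary-statistic entry points
(`t_test_from_summary`, `cv_from_summary`) let published "n, mean ± SD"
rows be re-analysed without raw data. CV uses the n−1 sample SD.

The stability analysis compares measurements taken within the first
10 minutes of the blood draw against those at ≥ 60 minutes (unpaired
pooled t by default; a paired per-subject-means variant is provided). The
10-minute "first block" is this package's definition — the source
convention is a block of measurements "immediately after" the draw, with
no stated width — and a window keeps the unpaired test calibrated where a
single-first-point-per-subject split would not be.

Published anchor values that depend on unavailable raw blood data
(normality p = 0.32, hematocrit correlation 0.26) are treated as simulator
parameters to emulate, not as reproducible targets.

## Problem sizes and tolerances

The test suite and `scripts/acceptance.py` use: 50 noiseless curves for
oracle recovery (k to 1e-6 relative, r² ≥ 1 − 1e-10); 200 replicates for
half-life recovery (bias < 1%, CV < 3% at 1% additive noise) and for
model discrimination (mono-exponential r² wins ≥ 95%); 2000 null
replicates for type-I calibration of the t-test and stability analysis
(acceptance band [0.03, 0.07] at α = 0.05); 10⁴ subjects for the cohort
CV check (15.1% ± 0.5 points). These sizes give Monte-Carlo error
comfortably inside each band while keeping a full run in seconds.

## Known limitations

* The bi-exponential peel degrades when `τ_slow` approaches the recording
  length (no observable baseline) or when components are < 2x separated;
  both conditions are flagged rather than fixed.
* The second-order model's doublet concentration [B] is never modelled
  explicitly — only the isolated-cell signal maps to light.
* No multiple-testing correction is applied anywhere (the analyses
  mirrored here apply none).
* The stability analysis assumes no within-hour autocorrelation beyond
  the subject level.
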