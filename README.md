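# eakit — erythrocyte aggregation kinetics from syllectograms

Red blood cells in low-shear conditions reversibly stick together
(erythrocyte aggregation, EA), first two-by-two into doublets, then into
rouleaux and three-dimensional clusters. The degree and speed of
aggregation shape whole-blood viscosity and rise with inflammation, which
makes the *kinetics* of aggregation a clinically interesting measurement —
if it can be captured quickly and reproducibly at the point of care.

One such measurement stirs the blood-collection tube to disperse all
aggregates, then records the backscattered light intensity as aggregation
restarts. Isolated cells backscatter far more light than aggregates, so
the recording — the **syllectogram** `I(t)` — decays. `eakit` implements
the analysis of that decay for researchers working on hemorheology and
aggregometry:

* **Kinetic models** (`eakit.kinetics`). Early, two-by-two aggregation is
  first-order in practice: `I(t) = A0·e^(−kt)` with rate constant `k`
  (1/s). The competing second-order mechanism predicts
  `1/I(t) = kt + 1/A0`. A full 20 s syllectogram is conventionally
  described by two exponentials above a baseline,
  `I(t) = I_f·e^(−t/τ_f) + I_s·e^(−t/τ_s) + I_0`, with time constants in
  seconds.
* **Fitting** (`eakit.fitting`). Nonlinear least squares of the
  mono-exponential on the first 5 s yields the headline statistic
  **EAK5s = ln 2 / k**, the aggregation half-life; OLS of `1/I` on `t`
  fits the second-order alternative; classical curve peeling initializes
  the five-constant bi-exponential decomposition; segment selection
  compares the 1.5 / 3 / 5 / 10 s windows by r².
* **Simulation** (`eakit.simulate`). A seeded generator emulating the
  device (noisy decays), subjects (repeat-measurement variability ~2.6%
  CV), study cohorts (healthy donors 2.51 ± 0.38 s; cardiology,
  ACS and non-ACS patient groups), hematocrit/half-life pairs with a
  prescribed correlation, and the tube-geometry shear-rate estimate
  (~1000 1/s at 1 Hz stirring).
* **Cohort statistics** (`eakit.cohort_stats`). Coefficients of
  variation, pooled/Welch two-tailed t-tests (from raw data or published
  summaries), Shapiro–Wilk normality, Pearson correlation, and the
  measurement-stability analysis over the hour after blood draw.
* **CLI** (`eakit.cli`): `eakit simulate | fit | cohort-sim |
  cohort-stats | shear`, all writing reproducibility manifests.

## Worked example

```python
from eakit import (MonoExpParams, NoiseSpec, simulate_syllectogram,
                   compute_eak5s, fit_inverse_linear, select_best_segment)

params = MonoExpParams(a0=1000.0, k=0.2762)        # healthy-donor kinetics
syl = simulate_syllectogram(params, duration=10.0, sampling_rate=100.0,
                            noise=NoiseSpec(sd=5.0, seed=1))

fit = compute_eak5s(syl)
print(f"EAK5s half-life : {fit.half_life_s:.3f} s (r2 = {fit.r2:.4f})")

inv = fit_inverse_linear(syl)
print(f"inverse-linear  : r2 = {inv.r2:.4f}")

sel = select_best_segment(syl)
print(f"best segment    : {sel.best_duration} s ({sel.rule})")
```

prints

```
EAK5s half-life : 2.511 s (r2 = 0.9995)
inverse-linear  : r2 = 0.8839
best segment    : 5.0 s (tie-shortest)
```

The fitted half-life recovers the generating value (ln 2 / 0.2762 =
2.510 s) to 0.04% despite the noise; the mono-exponential explains >99.9%
of the variance while the second-order model lags behind — the ordering
that justifies treating early aggregation as first-order. The same
analysis is available from the shell:

```sh
eakit simulate --preset healthy -n 10 --seed 7 -o runs/demo
eakit fit runs/demo -o runs/demo/report.json
eakit cohort-stats --summary healthy:51:2.51:0.38 --summary cardiology:14:1.73:0.34
```

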