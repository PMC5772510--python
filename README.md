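# ifpwv — pulse wave velocity from a single carotid waveform

Carotid-femoral pulse wave velocity (PWV) is the gold-standard index of
arterial stiffness, but measuring it requires tonometry at two arterial
sites plus ECG gating. `ifpwv` implements a machine-learning surrogate:
it estimates PWV (m/s) from **one uncalibrated carotid pressure
waveform** and a handful of routine clinical variables (age, brachial
blood pressure, body measurements). Because every waveform feature is
amplitude-invariant, the method is sensor-agnostic — any device that
records the *shape* of the carotid pulse will do.

The package is aimed at cardiovascular-signal researchers who want a
complete, testable reference implementation of the method, end to end,
with a synthetic-data layer standing in for access-restricted clinical
cohorts.

## The method

1. **Signal conditioning** (`ifpwv.preprocess`) — a 0.04 s moving
   average (exact spectral nulls at 25/50 Hz), envelope normalization
   onto [0, 1] to remove breathing wander, foot-to-foot beat
   segmentation with quality flags, and derivative-based dicrotic-notch
   detection.
2. **Intrinsic-frequency (IF) decomposition**
   (`ifpwv.intrinsic_frequency`) — each beat s(t) on [0, T) is fitted
   by a piecewise sinusoid with two constant angular frequencies
   switching at the notch time T₀:

   ```
   S(t) = a₁cos(ω₁t) + b₁sin(ω₁t) + p̄     0 ≤ t < T₀
   S(t) = a₂cos(ω₂t) + b₂sin(ω₂t) + p̄     T₀ ≤ t < T
   s.t.  continuity at T₀ and periodicity at T
   ```

   minimizing ‖s − S‖₂² — a nonconvex problem solved exactly in the
   coefficients at fixed (ω₁, ω₂) by equality-constrained least squares,
   with a log-spaced frequency grid plus Nelder-Mead refinement on top.
   ω₁ characterizes the heart-aorta coupling during systole, ω₂ the
   decoupled arterial tree during diastole.
3. **Feature engineering** (`ifpwv.features`) — the 21-entry candidate
   set V₀ (frequencies, period-normalized variants such as ω₁꜀ = ω₁√T₀
   and ω₁ₙ = ω₁T, shape fractions ρ, Cr, MCSF, envelope ratio Er, timing
   terms, and clinical covariates) and best-subset selection by
   exhaustive search under an extended BIC. The production subset V has
   12 features.
4. **Regression** (`ifpwv.model`) — bagging **without** replacement:
   1000 single-hidden-layer networks (|V| tanh units, 100 epochs,
   L2 penalty 0.01), each on a random 66% subsample; prediction is the
   member mean, convergence is judged by the out-of-bag RMSE plateau.
5. **Evaluation** (`ifpwv.evaluation`) — Bland-Altman agreement
   (bias ± 1.96 SD), RMSE, Pearson r, measured-PWV tertile breakdown,
   the Artery Society validation filter (BMI ≤ 30, PWV < 15 m/s), and
   closed-form propagation of independent error components:
   std(pred−ref) = √(std(pred−meas)² + std(ref−meas)²).

`ifpwv.synthetic_data` generates beats from the IF forward model (plus
a localized notch dip, baseline wander, and noise) and whole cohorts
whose PWV is a documented linear function of the features — so every
stage has ground truth to recover.

## Worked example

```python
import numpy as np
from ifpwv import (
    CohortSpec, CycleSpec, EnsembleConfig, agreement, fit_if,
    generate_cohort, generate_cycle, predict, stratified_split, train_ensemble,
)

# fit the IF model to one noisy synthetic beat (2% noise)
cycle = generate_cycle(CycleSpec(omega2=4.2, noise_sd=0.02, seed=1))
res = fit_if(cycle)
print(f"omega1 = {res.omega1:.2f} rad/s ({res.omega1/2/np.pi:.2f} Hz)")
print(f"omega2 = {res.omega2:.2f} rad/s ({res.omega2/2/np.pi:.2f} Hz)")
print(f"objective = {res.objective:.2e}, converged = {res.converged}")

# cohort -> stratified 80/20 split -> bagged ensemble -> agreement
cohort = generate_cohort(CohortSpec(n=500, seed=2))
train, test = stratified_split(cohort, seed=3)
model = train_ensemble(train, EnsembleConfig(n_estimators=100, seed=4))
stats = agreement(predict(model, test), test["PWV_measured"].to_numpy())
print(f"test RMSE = {stats.rmse:.3f} m/s")
print(f"bias = {stats.bias:+.3f} m/s, LoA = +/-{stats.loa_half_width:.3f} m/s")
```

Output:

```
omega1 = 12.56 rad/s (2.00 Hz)
omega2 = 4.11 rad/s (0.65 Hz)
objective = 3.25e-04, converged = True
test RMSE = 0.576 m/s
bias = -0.112 m/s, LoA = +/-1.113 m/s
```

The recovered frequencies match the generator's truth (ω₁ = 4π ≈ 12.57,
ω₂ = 4.2 rad/s) to within the noise; the held-out RMSE of 0.576 m/s
approaches the 0.5 m/s measurement noise injected by the cohort
generator, i.e. the model has learned essentially all of the systematic
PWV variation.

A command-line interface mirrors the library
(`ifpwv preprocess | fit-if | features | train | predict | evaluate |
simulate cohort`); run `ifpwv --help`.

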