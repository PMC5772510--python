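# Methods

## Model

A cardiac pressure cycle s(t), t ∈ [0, T), is approximated by an
intrinsic-mode function with two piecewise-constant angular frequencies
separated at the dicrotic notch T₀ (aortic valve closure):

    S(t) = (a₁ cos ω₁t + b₁ sin ω₁t + p̄)·1[0,T₀) + (a₂ cos ω₂t + b₂ sin ω₂t + p̄)·1[T₀,T)

subject to continuity at T₀,

    a₁ cos ω₁T₀ + b₁ sin ω₁T₀ = a₂ cos ω₂T₀ + b₂ sin ω₂T₀,

and periodicity at T,

    a₁ = a₂ cos ω₂T + b₂ sin ω₂T.

The fit minimizes the squared L2 residual over one period, discretized
as a uniform Riemann sum at the sample times (`objective = Δt·Σr²`;
refinement invariance is tested). ω₁ reflects ventricular-aortic
coupling during systole, ω₂ the arterial tree after valve closure; p̄ is
the cycle mean level. All waveform features fed to the regressor are
invariant to affine amplitude transforms, which is what makes
uncalibrated single-site recordings usable.

### Solving the fit

At fixed (ω₁, ω₂) the problem is linear least squares in
x = (a₁, b₁, a₂, b₂, p̄) with two homogeneous equality constraints
Cx = 0. Two independent solvers are implemented:

* **null-space elimination** (production path): an orthonormal basis N
  of ker C is computed by SVD and the reduced problem min‖ANz − s‖² is
  solved by `lstsq`; constraints hold by construction.
* **KKT system** (oracle path): the 7×7 stationarity system is solved
  directly. Because every sufficient statistic of the KKT matrix
  depends on only one of the two frequencies, the systems for an entire
  (ω₁, ω₂) grid are assembled by broadcasting and solved in one batched
  call — this makes a 200×200 brute-force grid cheap enough to serve as
  a routine test oracle.

The outer nonconvex search over (ω₁, ω₂) uses a 24×24 log-spaced grid
over [2π·0.5, 2π·20] rad/s (arterial pressure content lies below
~25 Hz) followed by Nelder-Mead refinement in log-frequency space,
clipped to the box; ties break to the lexicographically smallest pair,
and the refined objective is never allowed to exceed the best grid
value. There is no stochastic element in the fit.

Degenerate inputs: a constant cycle raises (frequencies unidentifiable);
near-rank-deficient designs are flagged `degenerate` rather than
silently returned.

## Signal conditioning

* **Smoothing**: centred moving average of total width 0.04 s,
  implemented with trapezoidal weights (half-weight endpoints). The
  discrete response then has *exact* nulls at multiples of 25 Hz for
  any sampling rate, matching the window's intended 50 Hz suppression;
  a flat odd-length boxcar would miss the null by the half-sample
  mismatch. At the trace edges the window shrinks symmetrically (mean
  over available samples), so constants are preserved exactly.
* **Normalization**: upper/lower envelopes through per-beat
  maxima/minima, interpolated with a natural cubic spline and continued
  linearly (with the boundary slope) beyond the outermost extrema, then
  (s − lower)/(upper − lower). A spline rather than a piecewise-linear
  envelope is used because linear interpolation of 0.25 Hz breathing
  wander leaves ~4% residual and injects slope kinks at the knots,
  which measurably destabilizes the derivative-based fiducials
  downstream.
* **Segmentation**: coarse feet are local minima below the 20th trace
  percentile separated by ≥ 0.3 s; each is refined to the 20%-of-pulse-
  height crossing of the following upstroke with sub-sample
  interpolation (the standard transit-time fiducial; a smoothed V-foot's
  argmin drifts with residual baseline tilt). Quality rules: duration
  within the physiologic 0.3–2.0 s band (30–200 bpm), normalized peak
  ≥ 0.8, and Pearson correlation ≥ 0.8 with the point-wise median beat
  template (this third rule is what catches spike artifacts, which
  survive the first two). Rejected beats are kept with a reason, never
  silently dropped.
* **Notch detection**: Savitzky-Golay (cubic, 25 ms window) smoothing
  and derivatives; candidates inside [0.15 T, 0.6 T] after the systolic
  peak, preferring the most prominent interior curvature (d²) peak,
  then the first local minimum, then the first upward zero crossing of
  d¹. The curvature maximum is primary because it marks the notch
  centre in both dip-type and shoulder-type notches, whereas a local
  minimum — when one exists at all — sits downstream by the amount
  needed for the dip flank to cancel the diastolic slope. A beat with
  no candidate in the admissible window is rejected ("no notch").

## Features and selection

V₀ has 21 entries: ω₁, ω₂; ω̄₁ = ω₁T₀, ω̄₂ = ω₂(T−T₀), ω₁꜀ = ω₁√T₀,
ω₂꜀ = ω₂T², ω₁ₙ = ω₁T, ω₂ₙ = ω₂T; ρ (notch height as a fraction of
pulse range), Er = √(a₁²+b₁²)/√(a₂²+b₂²), Cr = (p̄−min)/(max−min); T,
1/(T−T₀), 1/T₀; MCSF, AIx, SSN, RWAT, Age, Ps, Pd. The production
subset V (12 features) is {ω̄₂, ω₁꜀, ω₁ₙ, ρ, Er, MCSF, AIx, SSN, RWAT,
Age, Ps, Pd}.

Conventions decided here:

* **MCSF** = (mean − min)/(max − min). A literal "mean normalized by
  range" is scale-dependent for uncalibrated signals; the mean-minus-min
  form parallels the other shape fractions, is affine-invariant, and
  sits in [0, 1].
* **Angular frequencies are rad/s throughout.** Published population
  tables for these quantities are not internally unit-consistent
  (the ω₁꜀ and ω₁ₙ magnitudes imply ω₁ scales differing by ~50×), so no
  attempt is made to match their magnitudes; per-feature z-scoring
  before the regressor absorbs any monotone unit change anyway.
* **ρ** uses the raw cycle sample nearest T₀ (not the fitted model
  value), mirroring its definition directly on s(t).
* **Per-recording aggregation**: when several accepted beats exist for
  one subject, features are the per-feature median across beats.

**Best-subset selection** is exhaustive over all subsets for p ≤ 15
(branch-and-bound on the size-k minimum RSS above that, using RSS
monotonicity for pruning — exact, since the score depends on a subset
only through its size and RSS). The default score is the extended BIC
(Chen & Chen 2008) with γ = 1,

    EBIC = n·log(RSS/n) + (k+2)·log n + 2γ·log C(p, k),

because plain BIC's per-candidate spurious-inclusion probability
(P(χ²₁ > log n) ≈ 1.3% at n = 500) makes *exact* support recovery over
an exhaustive search unreliable; γ = 1 is the strongest standard member
of the family. Plain BIC remains available (`criterion="bic"`). RSS is
floored at 10⁻¹² of the response's total sum of squares so that
numerically exact fits are compared by the penalty, not by
floating-point noise in log-RSS. Ties (e.g. duplicated columns) resolve
to the lowest column index via the enumeration order.

## Ensemble

Defaults: 1000 members, 66% subsampling **without** replacement,
single hidden layer with |V| tanh units, linear output, 100 epochs,
L2 weight penalty 0.01. Features are z-scored with full-training-set
statistics (inputs only). Each member is a scikit-learn `MLPRegressor`
trained by L-BFGS — a batch optimizer of the same penalized
squared-error objective; the optimizer identity is incidental to the
method. Member subsamples and initializations derive from a
`SeedSequence`, so training is bit-reproducible for fixed (data,
config, seed).

The **out-of-bag trace** is cumulative: entry k is the RMSE, over all
training rows with at least one out-of-bag member among the first k, of
the mean prediction of those members. The trace's plateau is the
stopping diagnostic; with 66% bags the expected fraction of rows never
out-of-bag after k members is 0.66^k, so the trace is defined for all
rows almost immediately.

The 20% hold-back split is stratified on PWV deciles (quantile bins,
exact per-stratum allocation), so both partitions follow the population
PWV distribution; below ~4 rows per bin it falls back to a plain random
split with a warning.

## Evaluation

Agreement: bias = mean(pred − meas), SD with the n−1 denominator,
limits of agreement = bias ± 1.96·SD (normal 95%), RMSE, Pearson r
(flagged undefined for constant inputs). Tertile breakdown keys groups
by measured PWV with boundaries low ≤ 6.5, mid ∈ (6.5, 7.9), high
≥ 7.9 m/s; boundary values go to the outer groups. The Artery Society
validation filter keeps BMI ≤ 30 (path-length reliability) and
PWV < 15 m/s, reporting removal counts by reason; it is idempotent.

Error propagation treats the model-vs-sequential error and the
reference-vs-sequential device error as independent:
std(pred−ref) = √(std²(pred−meas) + std²(ref−meas)) and
E(pred−ref) = E(pred−meas) − E(ref−meas). With the published inputs
(1.05, 0.31, 0, −0.15 m/s) this gives 1.0948 ≈ 1.10 and +0.15 m/s.

## Synthetic data

The generator exists because the clinical cohorts this method was
developed on are access-restricted; it provides ground truth for every
recovery test.

* **Beat** (`CycleSpec`): the forward model above, with (a₂, b₂) solved
  exactly from the two constraints (or all four coefficients orthogonally
  projected onto the constraint set if supplied). Defaults — T = 0.85 s
  (~71 bpm), T₀ = 0.3376 s, ω₁ = 4π rad/s, ω₂ = 3.3 rad/s, a₁ = −0.45,
  b₁ = 0.1, p̄ = 0.55 — were chosen constructively: a sharp V-shaped
  foot (diastole still decaying where it meets a positive-slope
  upstroke, as in real carotid pulses; a flat sinusoidal trough would
  let baseline wander move any foot fiducial by tens of
  milliseconds), systolic peak mid-systole, notch at ~62% of pulse
  height. A Gaussian dip (depth 0.04, σ = 20 ms) is added at T₀ because
  the pure model is continuous there and would leave the notch detector
  untestable; consequently parameter-recovery tests use dip-free beats —
  the dip is a deliberate model violation. Noise is white Gaussian,
  scaled to a fraction of the noiseless range. Combinations with
  |sin ω₂(T−T₀)| ≈ 0 are rejected (the constraint system closing the
  model is singular there), and test grids keep that margin ≥ 0.45.
* **Recording**: concatenated beats (periodicity makes the junctions
  seamless), sinusoidal baseline wander (default 0.25 Hz — breathing),
  multiplicative amplitude modulation, optional heart-rate jitter; true
  beat boundaries are embedded.
* **Cohort** (`CohortSpec`): covariates are truncated normals targeting
  a middle-aged community population (Age 44.79 ± 11.32 y, Ps
  120.34 ± 14.53 mmHg, BMI 26.35 ± 4.64 kg/m², PWV centred at
  7.56 m/s). Each subject's beat is jittered (T ± 6%, T₀ ± 4%,
  frequencies ± 5%, diastolic centre 3.6 rad/s to keep the jitter inside
  the search box) and passed through the *actual* pipeline
  (generate → fit → features). Measured PWV = g(features) + N(0, 0.5 m/s)
  with g linear in Age, Ps, SSN, ω₁ₙ, ρ; each feature is centred at its
  population mean (exact truncated-normal means for the clinical
  covariates; a one-off 4000-draw reference run for the waveform
  features), so the population PWV mean equals the 7.56 m/s intercept by
  construction. The resulting PWV SD (~1.55 m/s) is somewhat below the
  target population's 1.93 because only five features carry signal.

### What passing tests do and do not show

The generator's beats *are* the fitting model (plus dip/noise), so
recovery tests validate the optimization and plumbing, not the model's
physiological adequacy. Real carotid waveforms contain reflected-wave
shoulders, non-stationary noise, probe-contact artifacts, and
notch morphologies the dip parameterization does not span; the cohort's
feature-to-PWV map is linear by construction, so the ensemble's ability
to reach the noise floor here does not bound its error on real
populations. What the tests do establish: the constrained solver is
exact, the outer search finds the global optimum to grid accuracy, the
feature formulas and their invariances are correct, the bagging/OOB
machinery matches brute-force recomputation, and the evaluation
statistics match closed forms.

## Problem sizes and tolerances

The shipped test suite and acceptance script use: 27-point recovery
grid (noise-free < 0.1%, 2% noise < 5% relative frequency error); 20
beats against a 200×200 brute-force frequency grid (objective ratio
≤ 1.001); 100 selection replicates (p = 10, n = 500, σ = 0.1; ≥ 95%
exact support); an end-to-end cohort of n = 2000 with a 100-member
ensemble (held-out RMSE within 20% of the injected 0.5 m/s noise;
OOB tail change < 2%); and n = 10⁵ sampled differences for the
agreement statistics (tolerances at 4 Monte-Carlo standard errors).
These sizes keep the whole suite around a minute of CPU while leaving
every check far from its tolerance in typical runs; constraint
satisfaction is asserted at 10⁻⁶ relative, solver cross-agreement at
10⁻⁸.

## Known limitations

* The IF fit assumes exactly two frequency regimes and a known T₀; a
  mislocated notch biases both frequencies (the per-beat median across
  a recording mitigates this).
* The frequency search box (0.5–20 Hz) censors fits whose true ω₂
  approaches the lower edge; the default cohort keeps its diastolic
  frequencies off the boundary for this reason.
* Quality rules (peak ≥ 0.8, template correlation ≥ 0.8, 20th-percentile
  feet) are declared conventions tuned for the synthetic regime; real
  deployments would revisit them against annotated recordings.
* AIx and RWAT are accepted as externally supplied covariates; the
  package does not compute them from the waveform.
* The prognostic (survival) use of estimated PWV is out of scope; so is
  any claim about real-cohort RMSE, which requires the restricted data.
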