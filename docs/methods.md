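# Methods

## The measurement model

A voxel carrying a grid-like signal responds to translational movement in
direction φ (allocentric, degrees) with a k-fold periodic modulation,
k = 6 being the grid signature:

    y_v(t) = baseline + drift(t) + a_v · cos(k(φ(t) − θ_v)) ⊛ h(t) + ε_v(t)

where θ_v ∈ [0°, 360°/k) is the voxel's preferred orientation, a_v ≥ 0 its
modulation amplitude, h the hemodynamic response and ε autocorrelated noise.
The estimator is the standard two-stage split-half procedure (GridCAT
lineage):

1. **GLM1** on the first half of each run: translation events enter as an
   unmodulated boxcar plus two parametric modulators, sin(kφ) and cos(kφ);
   rotations as a nuisance boxcar.  Per voxel, θ̂_v = atan2(β_sin, β_cos)/k
   and â_v = √(β_sin² + β_cos²).  The two-argument arctangent is essential:
   a plain arctan(β_sin/β_cos) would fold half the fundamental domain onto
   the other half.  The ROI orientation φ̄ is the â-weighted circular mean
   of the θ̂_v (computed on kθ, divided by k, wrapped to [0, 360/k)).
   Voxels with exactly zero amplitude have no orientation and are excluded
   from the average.
2. **GLM2** on the held-out second half: a single aligned modulator
   cos(k(φ − φ̄)).  Its coefficient, averaged (unweighted) over ROI voxels,
   is the GLS magnitude.  Cross-validation makes the magnitude signed:
   positive only when orientations generalize across halves.

Analyses run per hemisphere ROI, per run, per fold k ∈ {1, 5, 6, 7}
(k = 1 proxies head-direction tuning; 5 and 7 are specificity controls),
and per-participant values are the arithmetic mean over runs; a missing
cell in one run falls back to the other run with a logged flag.

### Carry-over regressors in GLM2

Hemodynamic tails of first-half events extend ~30 s past the split
boundary.  GLM2 is therefore built on the full-run timeline and restricted
to test-half rows, with the estimation half's translation/rotation boxcars
and quadrature pair included as nuisance columns.  Without them the tails
bias the magnitude (a planted noiseless amplitude of 0.8 reads as 0.82);
with them, noiseless recovery is exact to machine precision — the planted
series is then an exact linear combination of the design columns.  Because
translations and rotations tile the run without gaps, the boxcars' sum can
become constant (hence collinear with the intercept) on the restricted
rows when the trailing rest is short; redundant *nuisance* columns are
pruned until the design has full rank (the intercept and the aligned
modulator are never pruned).

## Design matrices and numerics

- Event regressors: boxcars on a 0.1 s microtime grid, convolved with a
  canonical double-gamma HRF (peak 6 s, undershoot 16 s, ratio 6:1, length
  32 s, peak normalized to 1, no derivatives), decimated to scan times
  (TR = 1 s).  With this scaling a GLM2 coefficient is in the same units as
  the planted amplitude.
- Drift: discrete-cosine high-pass basis with 128 s cutoff **plus an
  explicit linear regressor**.  The cosine set alone only approximates a
  linear trend; the explicit term makes the simulator's linear drift (and
  any added trend) absorb exactly, which the drift-immunity property test
  checks at 1e−6.
- Estimation: ordinary least squares per voxel, no prewhitening.  The
  simulator's AR(1) noise then only inflates coefficient variance; the
  null-calibration suite confirms group-level type-I error is preserved.
- Rank-deficient designs are rejected with the collinear columns named
  (QR with pivoting).
- Split rule: scans split at floor(n/2); events are assigned to a half by
  onset, an event straddling the boundary is truncated at the boundary and
  kept in the first half (numerically inert for GLM1 — the fit only sees
  pre-boundary rows — but keeps the bookkeeping exact).
- Circular arithmetic always operates in the fold's periodic space
  (period 360/k); distances via ((Δ + P/2) mod P) − P/2.
- The weighted circular mean raises an error when the resultant length is
  below 1e−12 (perfectly dispersed orientations have no mean).

## Stability and quality metrics

- **Temporal stability**: fraction of voxels with circular distance
  ≤ tolerance between the two halves' orientations; tolerance defaults to a
  quarter period, i.e. ±15° for k = 6, giving an analytic chance level of
  2·15/60 = 50%.  Undefined voxels are dropped from the denominator and
  counted.
- **Spatial stability**: Rayleigh test on kθ_v, unweighted; Z = nR̄² with
  the small-sample series approximation for p (clipped to (0, 1]).  The
  test suite cross-checks Z against `pingouin.circ_rayleigh` exactly and p
  approximately (pingouin uses Zar's exponential approximation instead of
  the series).
- **tSNR screening**: temporal mean over temporal SD per voxel; exclusion
  below Q1 − 1.5·IQR with linearly interpolated (type-7) quartiles, the
  default of numpy and R.  Constant series have undefined tSNR and are
  excluded.  The rule is scale-invariant.

## Group statistics

One-sample and Welch tests are one-sided (effect > null) by default — the
direction a positive grid signal implies, and the convention recoverable
from the published t/p pairs.  Cohen's d = t/√n (one-sample) or the
pooled-SD mean difference (two-sample).  Bayes factors are default
two-sided JZS t-test Bayes factors (Cauchy prior on effect size, width
r = 0.707): the Cauchy prior is expanded as a normal scale mixture and the
one-dimensional g-integral is evaluated as a likelihood *ratio* in log
space under a log-substitution, which stays accurate for arbitrarily large
|t| (relative quadrature tolerance 1e−9, convergence enforced at 1e−6).
The two-sample Bayes factor uses the pooled-t formulation with effective
n = n₁n₂/(n₁+n₂) even though the frequentist statistic is Welch's — the
deliberate mismatch mirrors common Bayesian t-test tooling.  Bonferroni
families divide α = 0.05 by family size (two 6-fold tests → 0.025; four
5-/7-fold control tests → 0.0125).  Pearson correlations report Fisher-z
confidence intervals.  Linear mixed-effects models are out of scope; the
pipeline emits tidy long-format tables ready for any standard mixed-model
tool.

## The synthetic testbed

### Trajectories

The generator reproduces the passive-navigation task design: a 160 × 160 vm
room, translation at 15 vm/s, rotation at 50°/s, 112 translation segments
per 620 s run with directions balanced over 10° bins (3–4 per bin).
Choices the task description leaves open, fixed once:

- direction within a bin: uniform (avoids comb artifacts at bin centers);
- ordering: randomized depth-first search requiring consecutive directions
  to differ with a shortest-arc turn in [10°, 170°] (exact reversals
  forbidden — which is what makes a 170° maximum attainable) and at least
  the minimum segment length of in-room headroom; a bounded step budget
  with cheap randomized restarts replaces deep backtracking;
- segment length: uniform on [25, 85] vm, clamped to the in-room run; the
  realized post-clamping mean is ≈ 50 vm, matching the reported realized
  segment statistics;
- start at room centre, 5 vm wall margin;
- a trailing stationary rest pads the schedule to exactly 620 s and is
  logged as an explicit event;
- coverage diagnostic: 1 × 1 vm bins, covered within a 3 vm disc or an
  8 vm cone of 65° *full* width about the heading, path sampled every
  0.5 vm (translations) / 2° (rotations); rest contributes the disc only.
  Default runs cover ~75–82% of the room.

Realized length/path totals are characterized but not treated as exact
targets (the published totals are not mutually consistent with the
published means).

### BOLD simulation

Voxel orientations are drawn von Mises around the group orientation in
k-fold angle space with concentration κ (κ = None plants θ_v = θ* exactly;
κ = 0 is uniform).  The neural signal a_v·cos(k(φ_e − θ_v)) enters as a
per-event boxcar through the same microtime/HRF path as the design
matrices, then baseline (100), linear drift (0.01 units/scan) and
stationary AR(1) Gaussian noise (marginal SD = noise_sd, lag-1 = 0.3) are
added.  An optional orientation drift shifts all θ_v at the run midpoint to
emulate temporal instability.  Defaults (48 voxels per hemisphere ROI,
amplitude 0.5, κ = 8, noise SD 1) describe a *strong, coherent* signal:
with κ = 8 the expected attenuation of the recovered magnitude is
I₁(8)/I₀(8) ≈ 0.935, and cohorts recover 0.467–0.470 for a planted 0.5,
matching that prediction.  What the simulator does **not** emulate: spatial
structure across voxels, motion artifacts and their correlates, multi-echo
physics, physiological noise spectra, non-canonical HRFs, or the weak
effect sizes of real EC data — so green synthetic tests demonstrate
estimator correctness and calibration, not that real-data effects of this
size exist.

## Validation experiments and their problem sizes

- Exact recovery: noiseless runs, machine-precision orientation and
  amplitude recovery, sign flip under an anti-phase reference.
- Parameter recovery / fold specificity: 100 participants, one run each,
  **each with an independently generated trajectory** — with a single
  shared path, path-specific cross-fold leakage of the planted 6-fold
  signal is common to everyone and control-fold means sit tens of SEs from
  zero; independent paths average that leakage out, so the experiment
  measures the estimator's fold specificity rather than one path's
  idiosyncrasies.
- Null calibration: 500 amplitude-zero cohorts of 40 participants
  (16 voxels) for the type-I error of the group test; stability metrics
  collected on the first 100 cohorts.  Sizes were chosen to keep the suite
  a few minutes long at the precision the bands require.

### Known limitation: residual control-fold bias

Even with independent trajectories, 5-/7-fold control magnitudes carry a
small negative bias (≈ −0.015 for a planted 6-fold amplitude of 0.5, i.e.
≈ 3%).  Mechanism: directions are balanced across each *run*, so the two
halves' directional imbalances are exactly complementary; the off-fold
pseudo-signals that the planted 6-fold modulation induces in the two halves
are therefore anticorrelated, and the cross-validated control-fold
magnitude inherits a negative expectation.  Diagnostics ruled out HRF
carry-over (adding oracle 6-fold tail regressors, or discarding the first
32 s of the test half, leaves the bias unchanged), and pure-noise cohorts
are unbiased.  The effect is intrinsic to split-half cross-validation of a
balanced design carrying a strong coherent off-fold signal; at realistic
(weak) signal levels it is negligible, but at the testbed's high SNR it can
reach ≈ 2 SE in a 100-participant cohort, and the corresponding
fold-specificity check sits at the edge of its band.

## Reproducibility

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; study-level seeds derive deterministically from
one master seed via `SeedSequence` with SHA-256 stream tags, and rerunning
a study configuration reproduces byte-identical output tables.  The study
manifest records seeds, configuration and SHA-256 checksums of every
output file.
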