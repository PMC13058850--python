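# gridglm — hexadirectional (grid-code) fMRI analysis with a synthetic testbed

Entorhinal grid cells fire on a hexagonal lattice, and their population
activity leaves a macroscopic signature in fMRI: BOLD activity in entorhinal
cortex (EC) modulates with the direction of movement φ through an
environment with a 60° (6-fold) periodicity.  `gridglm` implements the
standard two-stage, split-half estimator of this **grid-like signal (GLS)**
and everything needed to validate it without access to real participant
data — a generator of the passive-navigation task trajectories, a BOLD
simulator with planted directional modulation, stability and tSNR quality
metrics, and the group-level statistics (one-sided t-tests, Cohen's d, JZS
Bayes factors, Bonferroni families).

It is written for cognitive-neuroscience researchers who want a tested,
scriptable version of the GridCAT-style analysis, and for methodologists who
want to study its behavior under known ground truth.

## The estimator

Each run is split in half.  On the **estimation half**, GLM1 models every
translation event with two parametric modulators, sin(6φ) and cos(6φ).  Per
voxel *v*, the quadrature betas give

- orientation θ_v = atan2(β_sin, β_cos)/6 ∈ [0°, 60°), and
- amplitude a_v = √(β_sin² + β_cos²),

and the ROI orientation φ̄ is the amplitude-weighted circular mean of the
θ_v.  On the held-out **test half**, GLM2 carries the single aligned
modulator cos(6(φ − φ̄)); its coefficient, averaged over ROI voxels, is the
cross-validated GLS magnitude — positive when voxel orientations generalize
across halves.  Control symmetries (k = 1, 5, 7) use the same machinery
with 6 replaced by k.  Temporal stability is the fraction of voxels with
|θ_v(half 1) − θ_v(half 2)| ≤ 15° in 60°-space (chance 50%); spatial
stability is Rayleigh's Z = nR̄² on the voxel orientations; voxels are
screened by tSNR (excluded below Q1 − 1.5·IQR).

## Worked example

```python
from gridglm import (EnvironmentConfig, SimulationConfig,
                     generate_trajectory, simulate_bold, analyze_run)

traj = generate_trajectory(EnvironmentConfig(), seed=1)   # 112 balanced segments, 620 s
sim = SimulationConfig(orientation_concentration=None,    # all voxels share theta*
                       modulation_amplitude=0.8, noise_sd=0.0,
                       group_orientation=23.0, n_voxels=4)
run = simulate_bold(traj, sim, seed=2)
est, cell = analyze_run(run, traj.events, k=6)
print(round(est.phi_bar, 6), round(cell.magnitude, 6))
```

prints

```
23.0 0.8
```

— the estimator recovers the planted orientation (23°) and amplitude (0.8)
exactly on noiseless data.  The numbered drivers under `analysis/` run the
full program: `01_simulate_trajectories.py` regenerates the two fixed study
paths (112 segments in 3–4 per 10° bin, rotations 10–170°, ~75–82% room
coverage), `02_run_demo_study.py` analyzes a 20-participant cohort with a
planted 6-fold signal (recovered run-averaged magnitude 0.470 for a planted
0.5 at κ = 8, significant at the Bonferroni-corrected α = 0.025 while 5-
and 7-fold controls are not), `03_recovery_and_calibration.py` measures
parameter recovery (median orientation error 0.33°) and null calibration,
and `04_reported_statistics.py` recomputes the published group statistics
from their printed (t, n) inputs.

A `gridglm` console command exposes the same steps
(`simulate-trajectory`, `simulate-bold`, `run-gls`, `stability`,
`group-stats`, `demo`) for shell use with NIfTI/TSV inputs.

## Layout

```
src/gridglm/      library: trajectory, events, bold, design, glm, gridcode,
                  circular, stability, qc, stats, pipeline, io, cli
analysis/         numbered narrative drivers writing results/
tests/            pytest suite incl. end-to-end acceptance checks
docs/methods.md   model, assumptions, parameter choices, known limitations
```
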