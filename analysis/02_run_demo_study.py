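"""Simulate and analyze a full demo cohort with a planted 6-fold signal.

Twenty participants, two shared-trajectory runs each, left and right
hemisphere ROIs of 48 voxels carrying a hexadirectional modulation
(amplitude 0.5, voxel orientations von Mises kappa = 8 around a
per-participant group orientation) on top of baseline, drift and AR(1)
noise.  The full pipeline runs: tSNR screening, split-half GLM1/GLM2 for
folds 1/5/6/7, temporal + spatial stability, and group statistics with
Bonferroni families and JZS Bayes factors.

Outputs under results/demo_study/: gls.csv, participant.csv, stability.csv,
qc.csv, group_stats.csv, run events, manifest.json
"""

from pathlib import Path

from gridglm.pipeline import StudyConfig, run_study

RESULTS = Path(__file__).resolve().parents[1] / "results" / "demo_study"
MASTER_SEED = 2026


def main() -> None:
    cfg = StudyConfig(n_participants=20, n_runs=2, master_seed=MASTER_SEED)
    result = run_study(cfg, out_dir=RESULTS)
    print("group statistics (one-sample vs 0, one-sided; Welch when 2 groups):")
    print(result.group_stats.round(4).to_string(index=False))
    six = result.participant.query("fold == 6").magnitude
    print(
        f"\n6-fold run-averaged magnitude: mean {six.mean():.3f} "
        f"(planted amplitude 0.5, expected ~0.47 after kappa=8 dispersion)"
    )
    stab = result.stability
    print(
        f"temporal stability mean {stab.temporal_fraction.mean():.2%} "
        f"(chance 50%); spatial stability significant in "
        f"{(stab.rayleigh_p < 0.05).mean():.0%} of hemisphere-runs"
    )
    print(f"outputs -> {RESULTS}")


if __name__ == "__main__":
    main()
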