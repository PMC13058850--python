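"""End-to-end study orchestration: simulate -> analyze -> stability/QC -> group stats.

A study shares one fixed trajectory per run index across participants (as in
the task, where every participant experienced the same paths), simulates
per-participant BOLD runs for left and right hemisphere ROIs, runs the
two-stage grid-code analysis for every requested fold symmetry, derives
stability and tSNR QC tables, and closes with group-level statistics.  All
randomness derives deterministically from one master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .bold import BoldRun, simulate_bold
from .config import EnvironmentConfig, SimulationConfig
from .events import write_events
from .glm import fit_glm
from .gridcode import estimate_orientations, run_participant, split_run, _cached_design
from .qc import tsnr_filter
from .stability import spatial_stability, temporal_stability
from .stats import bonferroni_families, one_sample_test, welch_test
from .trajectory import generate_trajectory

logger = logging.getLogger(__name__)

HEMISPHERES = ("left", "right")


@dataclass
class StudyConfig:
    """Full specification of a simulated cohort study."""

    n_participants: int = 20
    n_runs: int = 2
    env: EnvironmentConfig = field(default_factory=EnvironmentConfig)
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    folds: Tuple[int, ...] = (1, 5, 6, 7)
    primary_fold: int = 6
    apply_qc: bool = True
    master_seed: int = 0
    # optional groups: label -> {"n": int, <SimulationConfig overrides>}
    groups: Optional[Dict[str, dict]] = None


@dataclass
class StudyResult:
    gls: pd.DataFrame  # per participant x hemisphere x run x fold
    participant: pd.DataFrame  # run-averaged
    stability: pd.DataFrame
    qc: pd.DataFrame
    group_stats: pd.DataFrame
    manifest: dict


def _seed_ints(master_seed: int, n: int, label: str) -> List[int]:
    """Deterministic child seeds below 2**31."""
    tag = int.from_bytes(hashlib.sha256(label.encode()).digest()[:4], "little")
    ss = np.random.SeedSequence([master_seed, tag % 2**31])
    return [int(s) % 2**31 for s in ss.generate_state(n)]


def _participant_groups(cfg: StudyConfig) -> List[Tuple[str, SimulationConfig]]:
    """Group label and simulation config for each participant, in order."""
    if not cfg.groups:
        return [("all", cfg.sim)] * cfg.n_participants
    out: List[Tuple[str, SimulationConfig]] = []
    for label, spec in cfg.groups.items():
        spec = dict(spec)
        n = spec.pop("n")
        sim = replace(cfg.sim, **spec)
        out.extend([(label, sim)] * n)
    return out


def half_orientations(run: BoldRun, events, k: int, roi_mask, design_cache=None):
    """GLM1 orientations of the ROI voxels in each data half (NaN = undefined)."""
    (h1, ev1), (h2, ev2) = split_run(run, events)
    out = []
    for half, ev in ((h1, ev1), (h2, ev2)):
        design = _cached_design(design_cache, ev, k, half.n_scans, half.tr)
        fit = fit_glm(half.data[np.asarray(roi_mask)], design)
        out.append(estimate_orientations(fit.beta("sin"), fit.beta("cos"), k))
    return out[0], out[1]


def simulate_participant_runs(
    trajectories,
    sim: SimulationConfig,
    seed: int,
    rng_orientation: np.random.Generator,
) -> Tuple[List[Tuple[BoldRun, pd.DataFrame]], Dict[str, np.ndarray]]:
    """Simulate all runs of one participant (both hemisphere ROIs stacked).

    Each hemisphere gets its own group orientation, drawn uniformly over the
    fold's fundamental domain, held fixed across runs.
    """
    n_vox = sim.n_voxels
    theta_star = {
        hemi: float(rng_orientation.uniform(0.0, sim.period)) for hemi in HEMISPHERES
    }
    masks = {
        "left": np.arange(2 * n_vox) < n_vox,
        "right": np.arange(2 * n_vox) >= n_vox,
    }
    run_seeds = _seed_ints(seed, 2 * len(trajectories), "runs")
    runs = []
    for r, traj in enumerate(trajectories):
        parts, truth_theta, truth_amp = [], [], []
        for h, hemi in enumerate(HEMISPHERES):
            hemi_sim = replace(sim, group_orientation=theta_star[hemi])
            part = simulate_bold(traj, hemi_sim, seed=run_seeds[2 * r + h])
            parts.append(part.data)
            truth_theta.extend(part.ground_truth["theta"])
            truth_amp.extend(part.ground_truth["amplitude"])
        truth = {
            "fold": sim.fold,
            "group_orientation": theta_star,
            "theta": truth_theta,
            "amplitude": truth_amp,
        }
        labels = np.array(["left"] * n_vox + ["right"] * n_vox)
        run = BoldRun(
            data=np.vstack(parts), tr=sim.tr, ground_truth=truth, mask_labels=labels
        )
        runs.append((run, traj.events))
    return runs, masks


def run_study(cfg: StudyConfig, out_dir: Optional[Path] = None) -> StudyResult:
    """Execute a full simulated study; fully reproducible from the config."""
    traj_seeds = _seed_ints(cfg.master_seed, cfg.n_runs, "trajectories")
    trajectories = [generate_trajectory(cfg.env, s) for s in traj_seeds]
    groups = _participant_groups(cfg)
    part_seeds = _seed_ints(cfg.master_seed, len(groups), "participants")
    design_cache: dict = {}
    gls_rows, part_rows, stab_rows, qc_rows = [], [], [], []
    warnings: List[str] = []

    for p, ((glabel, sim), pseed) in enumerate(zip(groups, part_seeds)):
        pid = f"sub-{p + 1:03d}"
        rng = np.random.default_rng(pseed)
        runs, masks = simulate_participant_runs(trajectories, sim, pseed, rng)
        # QC: a voxel must survive the tSNR rule in every run to be analyzed
        keep = np.ones(runs[0][0].n_voxels, dtype=bool)
        for r, (run, _) in enumerate(runs):
            qcr = tsnr_filter(run)
            qc_rows.append(
                dict(
                    participant=pid,
                    run=r,
                    n_voxels=run.n_voxels,
                    n_excluded=len(qcr.excluded),
                    tsnr_median=float(np.nanmedian(qcr.tsnr)),
                    threshold=qcr.threshold,
                )
            )
            if cfg.apply_qc:
                keep &= qcr.keep
        eff_masks = {h: m & keep for h, m in masks.items()}
        result = run_participant(
            runs, eff_masks, cfg.folds, design_cache=design_cache, participant=pid
        )
        warnings.extend(result.warnings)
        cells = result.cells.copy()
        cells.insert(1, "group", glabel)
        gls_rows.append(cells)
        part = result.participant.copy()
        part.insert(1, "group", glabel)
        part_rows.append(part)
        for r, (run, events) in enumerate(runs):
            for hemi, mask in eff_masks.items():
                est1, est2 = half_orientations(
                    run, events, cfg.primary_fold, mask, design_cache
                )
                ts = temporal_stability(est1.theta, est2.theta, cfg.primary_fold)
                ss = spatial_stability(est1.theta, cfg.primary_fold)
                stab_rows.append(
                    dict(
                        participant=pid,
                        group=glabel,
                        hemisphere=hemi,
                        run=r,
                        fold=cfg.primary_fold,
                        temporal_fraction=ts.temporal_fraction,
                        chance_level=ts.chance_level,
                        rayleigh_z=ss.rayleigh_z,
                        rayleigh_p=ss.rayleigh_p,
                        n_voxels=ts.n_voxels,
                    )
                )

    gls = pd.concat(gls_rows, ignore_index=True)
    participant = pd.concat(part_rows, ignore_index=True)
    stability = pd.DataFrame(stab_rows)
    qc = pd.DataFrame(qc_rows)
    group_stats = compute_group_stats(participant, primary_fold=cfg.primary_fold)

    manifest = {
        "master_seed": cfg.master_seed,
        "trajectory_seeds": traj_seeds,
        "participant_seeds": part_seeds,
        "config": _config_dict(cfg),
        "warnings": warnings,
        "files": {},
    }
    result = StudyResult(gls, participant, stability, qc, group_stats, manifest)
    if out_dir is not None:
        _write_outputs(result, trajectories, Path(out_dir))
    return result


def simulate_recovery_cohort(
    n_participants: int,
    seed: int,
    sim: Optional[SimulationConfig] = None,
    env: Optional[EnvironmentConfig] = None,
    folds: Sequence[int] = (5, 6, 7),
) -> pd.DataFrame:
    """Parameter-recovery cohort: one run per participant, each with its own
    independently generated trajectory and group orientation.

    Per-participant trajectories make trajectory-specific cross-fold leakage
    average out across the cohort, so the fold columns measure the method's
    fold specificity rather than the idiosyncrasies of one path.  Returns a
    tidy frame with one row per participant x fold: magnitude, phi_bar, the
    planted orientation and the circular estimation error (6-fold space).
    """
    from .circular import circ_dist
    from .gridcode import analyze_run

    sim = sim or SimulationConfig()
    env = env or EnvironmentConfig()
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_participants):
        traj = generate_trajectory(env, int(rng.integers(2**31)))
        theta = float(rng.uniform(0.0, sim.period))
        run = simulate_bold(
            traj,
            replace(sim, group_orientation=theta),
            seed=int(rng.integers(2**31)),
        )
        cache: dict = {}
        for k in folds:
            est, cell = analyze_run(run, traj.events, k, design_cache=cache)
            rows.append(
                dict(
                    participant=p,
                    fold=k,
                    magnitude=cell.magnitude,
                    phi_bar=cell.phi_bar,
                    theta_star=theta,
                    phi_error=float(circ_dist(cell.phi_bar, theta, k)),
                )
            )
    return pd.DataFrame(rows)


def null_calibration(
    n_replicates: int,
    n_participants: int,
    seed: int,
    sim: Optional[SimulationConfig] = None,
    env: Optional[EnvironmentConfig] = None,
    fold: int = 6,
    alpha: float = 0.05,
    stability_replicates: Optional[int] = None,
) -> dict:
    """Calibration of the pipeline on amplitude-zero (pure noise) cohorts.

    Every replicate simulates a cohort on one shared trajectory, runs the
    full two-stage analysis per participant, and applies the group-level
    one-sample test.  Returns the empirical type-I error of that test, the
    rate of significant Rayleigh (spatial-stability) tests across all
    participants, and the mean temporal-stability fraction.  The stability
    metrics need fewer samples than the type-I rate, so they are collected
    on the first ``stability_replicates`` replicates only (default: all).
    """
    from .gridcode import analyze_run
    from .stability import spatial_stability, temporal_stability

    sim = replace(sim or SimulationConfig(n_voxels=16), modulation_amplitude=0.0)
    env = env or EnvironmentConfig()
    rng = np.random.default_rng(seed)
    traj = generate_trajectory(env, int(rng.integers(2**31)))
    cache: dict = {}
    rejections = 0
    rayleigh_sig, temporal = [], []
    if stability_replicates is None:
        stability_replicates = n_replicates
    for rep in range(n_replicates):
        mags = []
        for p in range(n_participants):
            run = simulate_bold(traj, sim, seed=int(rng.integers(2**31)))
            est, cell = analyze_run(run, traj.events, fold, design_cache=cache)
            mags.append(cell.magnitude)
            if rep < stability_replicates:
                rayleigh_sig.append(
                    spatial_stability(est.theta, fold).rayleigh_p < alpha
                )
                est1, est2 = half_orientations(
                    run, traj.events, fold, np.ones(run.n_voxels, bool), cache
                )
                temporal.append(
                    temporal_stability(est1.theta, est2.theta, fold).temporal_fraction
                )
        if one_sample_test(np.asarray(mags), compute_bf=False).p < alpha:
            rejections += 1
    return {
        "type_i_error": rejections / n_replicates,
        "rayleigh_rate": float(np.mean(rayleigh_sig)),
        "temporal_fraction": float(np.mean(temporal)),
        "n_replicates": n_replicates,
        "n_participants": n_participants,
    }


def compute_group_stats(participant: pd.DataFrame, primary_fold: int = 6) -> pd.DataFrame:
    """One-sample tests per hemisphere x fold with Bonferroni families, and
    Welch group comparisons at the primary fold when two groups are present."""
    rows = []
    tests, families = {}, {}
    for (hemi, fold), sub in participant.groupby(["hemisphere", "fold"]):
        res = one_sample_test(sub["magnitude"].dropna().to_numpy())
        tid = f"onesample_{hemi}_{fold}fold"
        if fold == primary_fold:
            families[tid] = "primary"
        elif fold in (5, 7):
            families[tid] = "control"
        else:
            families[tid] = f"{fold}fold"
        tests[tid] = res.p
        rows.append(
            dict(
                test=tid, family=families[tid], t=res.t, df=res.df, p=res.p,
                d=res.d, bf10=res.bf10, bf01=res.bf01, n=res.n,
            )
        )
    # groups compared in order of first appearance (first-listed minus second)
    glabels = list(pd.unique(participant["group"].dropna())) if "group" in participant else []
    if len(glabels) == 2:
        for hemi, sub in participant[participant["fold"] == primary_fold].groupby("hemisphere"):
            a = sub[sub["group"] == glabels[0]]["magnitude"].dropna().to_numpy()
            b = sub[sub["group"] == glabels[1]]["magnitude"].dropna().to_numpy()
            res = welch_test(a, b)
            tid = f"welch_{hemi}_{primary_fold}fold_{glabels[0]}_vs_{glabels[1]}"
            families[tid] = "group_difference"
            tests[tid] = res.p
            rows.append(
                dict(
                    test=tid, family="group_difference", t=res.t, df=res.df,
                    p=res.p, d=res.d, bf10=res.bf10, bf01=res.bf01,
                    n=res.n1 + res.n2,
                )
            )
    flags = bonferroni_families(tests, families)
    out = pd.DataFrame(rows)
    out["alpha_corrected"] = [flags[t][1] for t in out["test"]]
    out["significant"] = [flags[t][2] for t in out["test"]]
    return out


def _config_dict(cfg: StudyConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["env"]["segment_length_range"] = list(d["env"]["segment_length_range"])
    d["folds"] = list(d["folds"])
    return d


def _write_outputs(result: StudyResult, trajectories, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    for r, traj in enumerate(trajectories):
        p = out_dir / f"run-{r + 1}_events.tsv"
        write_events(traj, p)
        files[p.name] = _sha256(p)
    tables = {
        "gls.csv": result.gls,
        "participant.csv": result.participant,
        "stability.csv": result.stability,
        "qc.csv": result.qc,
        "group_stats.csv": result.group_stats,
    }
    for name, table in tables.items():
        p = out_dir / name
        table.to_csv(p, index=False)
        files[name] = _sha256(p)
    result.manifest["files"] = files
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(result.manifest, fh, indent=1, default=str)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()
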