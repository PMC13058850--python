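"""Two-stage cross-validated estimation of grid-like directional signals.

Stage one (GLM1, estimation half): quadrature betas give each voxel's
orientation theta_v = atan2(beta_sin, beta_cos)/k in [0, 360/k) and amplitude
a_v = sqrt(beta_sin**2 + beta_cos**2); the ROI orientation phi_bar is the
amplitude-weighted circular mean.  Stage two (GLM2, held-out test half): the
coefficient of the aligned modulator cos(k*(phi - phi_bar)), averaged over
ROI voxels, is the grid-like signal (GLS) magnitude.  Positive magnitudes
indicate orientations that generalize across data halves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple
import logging

import numpy as np
import pandas as pd

from .bold import BoldRun
from .circular import UndefinedOrientationError, weighted_mean_orientation, wrap
from .design import (
    DesignMatrix,
    build_crossval_test_design,
    build_design,
    build_test_design,
)
from .glm import fit_glm

logger = logging.getLogger(__name__)


@dataclass
class GridEstimate:
    """Per-voxel orientations/amplitudes and the ROI mean orientation."""

    theta: np.ndarray  # degrees in [0, 360/k); NaN where undefined
    amplitude: np.ndarray
    valid: np.ndarray  # False where both betas were exactly zero
    fold: int
    phi_bar: Optional[float] = None
    resultant: Optional[float] = None
    roi: Optional[str] = None
    half: Optional[str] = None


@dataclass
class GlsCell:
    """One ROI x run x fold cross-validated magnitude."""

    magnitude: float
    phi_bar: float
    n_voxels: int
    per_voxel: np.ndarray


@dataclass
class GLSResult:
    """Tidy per-cell table and the run-averaged per-participant table."""

    cells: pd.DataFrame  # hemisphere, run, fold, phi_bar, magnitude, n_voxels
    participant: pd.DataFrame  # hemisphere, fold, magnitude (mean over runs)
    warnings: List[str] = field(default_factory=list)


def estimate_orientations(beta_sin, beta_cos, k: int) -> GridEstimate:
    """Voxel orientations and amplitudes from quadrature betas.

    The quadrant-aware two-argument arctangent is required: a plain
    arctan(beta_sin/beta_cos) would fold half the fundamental domain onto
    the other half.  Voxels with both betas exactly zero are flagged invalid.
    """
    bs = np.asarray(beta_sin, dtype=float)
    bc = np.asarray(beta_cos, dtype=float)
    if not (np.all(np.isfinite(bs)) and np.all(np.isfinite(bc))):
        raise ValueError("betas must be finite")
    amp = np.hypot(bs, bc)
    valid = amp > 0
    theta = np.full(bs.shape, np.nan)
    theta[valid] = wrap(np.rad2deg(np.arctan2(bs[valid], bc[valid])) / k, k)
    return GridEstimate(theta=theta, amplitude=amp, valid=valid, fold=k)


def mean_orientation(theta, weights, k: int) -> Tuple[float, float]:
    """Amplitude-weighted circular mean orientation, see :mod:`gridglm.circular`."""
    return weighted_mean_orientation(theta, weights, k)


def split_run(
    run: BoldRun, events: pd.DataFrame
) -> Tuple[Tuple[BoldRun, pd.DataFrame], Tuple[BoldRun, pd.DataFrame]]:
    """Split a run into estimation (first) and test (second) halves.

    Scans split at floor(n_scans/2); events are assigned to a half by onset,
    an event straddling the boundary is truncated at the boundary and kept
    in the first half, and second-half onsets are re-referenced to the start
    of that half.
    """
    if run.n_scans <= 2:
        raise ValueError("run too short to split")
    cut_scan = run.n_scans // 2
    cut_time = cut_scan * run.tr
    first = events[events["onset"] < cut_time].copy()
    first["duration"] = np.minimum(
        first["duration"].to_numpy(float),
        cut_time - first["onset"].to_numpy(float),
    )
    second = events[events["onset"] >= cut_time].copy()
    second["onset"] = second["onset"].to_numpy(float) - cut_time
    half1 = BoldRun(run.data[:, :cut_scan], tr=run.tr, ground_truth=run.ground_truth,
                    mask_labels=run.mask_labels)
    half2 = BoldRun(run.data[:, cut_scan:], tr=run.tr, ground_truth=run.ground_truth,
                    mask_labels=run.mask_labels)
    for tag, half_ev in (("estimation", first), ("test", second)):
        trans = half_ev[half_ev["trial_type"] == "translation"]
        if len(trans) and trans["direction"].nunique() < 2:
            logger.warning("%s half has fewer than 2 distinct directions", tag)
    return (half1, first), (half2, second)


def gls_magnitude(
    test_run: BoldRun,
    events: pd.DataFrame,
    phi_bar: float,
    k: int,
    roi_mask: Optional[np.ndarray] = None,
    base_design: Optional[DesignMatrix] = None,
) -> GlsCell:
    """Cross-validated GLS magnitude of one ROI on the test half.

    Fits GLM2 per voxel and averages the aligned-modulator coefficient over
    the ROI (unweighted voxel mean).
    """
    data = test_run.data if roi_mask is None else test_run.data[np.asarray(roi_mask)]
    if data.shape[0] == 0:
        raise ValueError("empty ROI")
    design = build_test_design(
        events, k, phi_bar, n_scans=data.shape[1], tr=test_run.tr, base=base_design
    )
    fit = fit_glm(data, design)
    per_voxel = fit.beta("aligned")
    return GlsCell(
        magnitude=float(per_voxel.mean()),
        phi_bar=float(phi_bar),
        n_voxels=int(data.shape[0]),
        per_voxel=per_voxel,
    )


def _events_key(events: pd.DataFrame) -> int:
    return int(
        pd.util.hash_pandas_object(
            events[["onset", "duration"]].reset_index(drop=True), index=False
        ).sum()
    )


def _cached_design(cache, events, k, n_scans, tr) -> DesignMatrix:
    if cache is None:
        return build_design(events, k, n_scans, tr)
    key = (_events_key(events), k, n_scans, round(tr, 9))
    if key not in cache:
        cache[key] = build_design(events, k, n_scans, tr)
    return cache[key]


def analyze_run(
    run: BoldRun,
    events: pd.DataFrame,
    k: int,
    roi_mask: Optional[np.ndarray] = None,
    design_cache: Optional[dict] = None,
):
    """Full two-stage analysis of one run for one ROI and one fold.

    GLM1 runs on the first half (orientation estimation); GLM2 runs on the
    held-out second half with carry-over nuisance regressors for the
    hemodynamic tails of first-half events.  Returns (GridEstimate with
    phi_bar filled, GlsCell).
    """
    (est_run, est_ev), _ = split_run(run, events)
    d_est = _cached_design(design_cache, est_ev, k, est_run.n_scans, est_run.tr)
    data = run.data if roi_mask is None else run.data[np.asarray(roi_mask)]
    if data.shape[0] == 0:
        raise ValueError("empty ROI")
    cut = run.n_scans // 2
    fit = fit_glm(data[:, :cut], d_est)
    est = estimate_orientations(fit.beta("sin"), fit.beta("cos"), k)
    phi_bar, resultant = mean_orientation(
        est.theta[est.valid], est.amplitude[est.valid], k
    )
    est.phi_bar, est.resultant = phi_bar, resultant
    cut_time = cut * run.tr
    est_full = events[events["onset"] < cut_time]
    test_full = events[events["onset"] >= cut_time]
    d_test = build_crossval_test_design(
        est_full,
        test_full,
        k,
        phi_bar,
        n_scans=run.n_scans,
        cut_scan=cut,
        tr=run.tr,
        est_base=_cached_design(design_cache, est_full, k, run.n_scans, run.tr),
        test_base=_cached_design(design_cache, test_full, k, run.n_scans, run.tr),
    )
    fit2 = fit_glm(data[:, cut:], d_test)
    per_voxel = fit2.beta("aligned")
    cell = GlsCell(
        magnitude=float(per_voxel.mean()),
        phi_bar=float(phi_bar),
        n_voxels=int(data.shape[0]),
        per_voxel=per_voxel,
    )
    return est, cell


def run_participant(
    runs: Sequence[Tuple[BoldRun, pd.DataFrame]],
    masks: Dict[str, np.ndarray],
    folds: Iterable[int] = (6,),
    design_cache: Optional[dict] = None,
    participant: Optional[str] = None,
) -> GLSResult:
    """Two-stage analysis per hemisphere x run x fold, then run-averaged.

    ``masks`` maps hemisphere/ROI labels to disjoint boolean voxel masks.
    Per-cell failures (e.g. an undefined mean orientation) are recorded as
    missing rather than aborting the participant.
    """
    if len(runs) == 0:
        raise ValueError("at least one run is required")
    mask_arrays = {lab: np.asarray(m, dtype=bool) for lab, m in masks.items()}
    stacked = np.sum(list(mask_arrays.values()), axis=0)
    if np.any(stacked > 1):
        raise ValueError("ROI masks overlap")
    rows, warns = [], []
    for run_idx, (run, events) in enumerate(runs):
        for k in folds:
            for label, mask in mask_arrays.items():
                try:
                    est, cell = analyze_run(
                        run, events, k, roi_mask=mask, design_cache=design_cache
                    )
                    rows.append(
                        dict(
                            participant=participant,
                            hemisphere=label,
                            run=run_idx,
                            fold=k,
                            phi_bar=cell.phi_bar,
                            magnitude=cell.magnitude,
                            n_voxels=cell.n_voxels,
                        )
                    )
                except (UndefinedOrientationError, ValueError) as exc:
                    warns.append(
                        f"run {run_idx}, fold {k}, {label}: {exc}"
                    )
                    rows.append(
                        dict(
                            participant=participant,
                            hemisphere=label,
                            run=run_idx,
                            fold=k,
                            phi_bar=np.nan,
                            magnitude=np.nan,
                            n_voxels=int(mask.sum()),
                        )
                    )
    cells = pd.DataFrame(rows)
    if cells["magnitude"].isna().any():
        warns.append("participant has missing cells; run average uses available runs")
    part = (
        cells.groupby(["hemisphere", "fold"], as_index=False)
        .agg(magnitude=("magnitude", "mean"), n_runs=("magnitude", "count"))
    )
    part.insert(0, "participant", participant)
    return GLSResult(cells=cells, participant=part, warnings=warns)
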