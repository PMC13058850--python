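"""Fold-k quadrature GLM design matrices.

The estimation model (GLM1) carries two parametric modulators on the
translation events -- sin(k*phi) and cos(k*phi) of the allocentric movement
direction phi -- whose fitted coefficients give each voxel's k-fold
orientation and amplitude.  The test model (GLM2) carries the single aligned
modulator cos(k*(phi - phi_bar)) against a reference orientation phi_bar.

Event regressors are built as boxcars on a 0.1 s microtime grid, convolved
with a canonical double-gamma hemodynamic response, then decimated to scan
times.  Rotations enter as an unmodulated nuisance boxcar.  Drift is removed
by a discrete-cosine high-pass set (128 s cutoff) plus an explicit linear
term, so a linear trend in the data is absorbed exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

MICROTIME_DT = 0.1
HRF_ID = "double-gamma(6,16,1:6)"


class DesignError(ValueError):
    pass


def double_gamma_hrf(
    dt: float = MICROTIME_DT,
    duration: float = 32.0,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    dispersion: float = 1.0,
    undershoot_ratio: float = 6.0,
) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``dt``, peak normalized to 1."""
    t = np.arange(0.0, duration, dt)
    h = sps.gamma.pdf(t, peak_delay / dispersion, scale=dispersion)
    h -= sps.gamma.pdf(t, undershoot_delay / dispersion, scale=dispersion) / undershoot_ratio
    return h / h.max()


def convolved_regressor(
    onsets,
    durations,
    values,
    n_scans: int,
    tr: float,
    dt: float = MICROTIME_DT,
    hrf: Optional[np.ndarray] = None,
) -> np.ndarray:
    """HRF-convolved boxcar regressor sampled at scan times.

    Each event contributes a boxcar of height ``values[i]`` over
    [onset, onset + duration) on the microtime grid.  Events extending beyond
    the scan window are rejected.
    """
    if hrf is None:
        hrf = double_gamma_hrf(dt=dt)
    window = n_scans * tr
    n_micro = int(round(window / dt))
    box = np.zeros(n_micro)
    for onset, dur, val in zip(
        np.atleast_1d(onsets), np.atleast_1d(durations), np.atleast_1d(values)
    ):
        if onset < 0 or onset + dur > window + 1e-9:
            raise DesignError(
                f"event at onset {onset:.3f} s (duration {dur:.3f} s) extends "
                f"beyond the {window:.1f} s scan window"
            )
        a = int(round(onset / dt))
        b = min(int(round((onset + dur) / dt)), n_micro)
        box[a:b] += val
    conv = np.convolve(box, hrf)[:n_micro]
    idx = np.minimum(np.round(np.arange(n_scans) * tr / dt).astype(int), n_micro - 1)
    return conv[idx]


def dct_drift_basis(n_scans: int, tr: float, cutoff: float = 128.0) -> np.ndarray:
    """Discrete-cosine high-pass set (periods longer than ``cutoff`` s)."""
    order = int(np.floor(2.0 * n_scans * tr / cutoff))
    i = np.arange(n_scans)
    cols = [
        np.sqrt(2.0 / n_scans) * np.cos(np.pi * (2 * i + 1) * r / (2.0 * n_scans))
        for r in range(1, order + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_scans, 0))


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # scans x regressors
    names: List[str]
    tr: float
    fold: int
    hrf_id: str = HRF_ID
    drift: str = "dct-128s+linear"

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.names):
            raise DesignError("column count does not match regressor names")
        if not np.all(np.isfinite(self.matrix)):
            raise DesignError("design matrix contains non-finite entries")
        if self.names.count("intercept") != 1:
            raise DesignError("design must contain exactly one intercept")

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.names)


def _event_arrays(events: pd.DataFrame, trial_type: str):
    sel = events[events["trial_type"] == trial_type]
    return (
        sel["onset"].to_numpy(float),
        sel["duration"].to_numpy(float),
        sel["direction"].to_numpy(float) if "direction" in sel else np.zeros(len(sel)),
    )


def build_design(
    events: pd.DataFrame,
    k: int,
    n_scans: int,
    tr: float,
    phase_offset: float = 0.0,
    highpass_cutoff: float = 128.0,
    dt: float = MICROTIME_DT,
) -> DesignMatrix:
    """Estimation (GLM1) design: quadrature modulators plus nuisance set.

    Regressors, in order: intercept; unmodulated translation boxcar;
    translation boxcar modulated by sin(k*(phi - phase_offset)) and by
    cos(k*(phi - phase_offset)); unmodulated rotation boxcar (when rotation
    events exist); linear drift; discrete-cosine high-pass set.
    """
    if k < 1:
        raise DesignError("fold k must be >= 1")
    hrf = double_gamma_hrf(dt=dt)
    t_on, t_dur, t_dir = _event_arrays(events, "translation")
    if len(t_on) == 0:
        raise DesignError("events contain no translation events")
    ang = np.deg2rad(k * (t_dir - phase_offset))
    cols = [np.ones(n_scans)]
    names = ["intercept"]
    cols.append(convolved_regressor(t_on, t_dur, np.ones_like(t_on), n_scans, tr, dt, hrf))
    names.append("translation")
    cols.append(convolved_regressor(t_on, t_dur, np.sin(ang), n_scans, tr, dt, hrf))
    names.append("sin")
    cols.append(convolved_regressor(t_on, t_dur, np.cos(ang), n_scans, tr, dt, hrf))
    names.append("cos")
    r_on, r_dur, _ = _event_arrays(events, "rotation")
    if len(r_on):
        cols.append(convolved_regressor(r_on, r_dur, np.ones_like(r_on), n_scans, tr, dt, hrf))
        names.append("rotation")
    lin = np.arange(n_scans) / max(n_scans - 1, 1) - 0.5
    cols.append(lin)
    names.append("drift_linear")
    dct = dct_drift_basis(n_scans, tr, highpass_cutoff)
    for r in range(dct.shape[1]):
        cols.append(dct[:, r])
        names.append(f"dct{r + 1:02d}")
    return DesignMatrix(np.column_stack(cols), names, tr=tr, fold=k)


def build_test_design(
    events: pd.DataFrame,
    k: int,
    phi_bar: float,
    n_scans: int,
    tr: float,
    base: Optional[DesignMatrix] = None,
    **kwargs,
) -> DesignMatrix:
    """Test (GLM2) design with the single aligned modulator cos(k*(phi - phi_bar)).

    Because per-event modulation, boxcar accumulation, convolution and
    decimation are all linear, the aligned column is the exact combination
    cos(k*phi_bar) * [cos column] + sin(k*phi_bar) * [sin column] of the
    quadrature design, which may be supplied as ``base`` to avoid rebuilding.
    """
    if base is None:
        base = build_design(events, k, n_scans, tr, **kwargs)
    if base.fold != k:
        raise DesignError("base design was built for a different fold")
    a = np.deg2rad(k * phi_bar)
    aligned = np.cos(a) * base.column("cos") + np.sin(a) * base.column("sin")
    keep = [i for i, n in enumerate(base.names) if n not in ("sin", "cos")]
    insert_at = base.names.index("sin")
    cols, names = [], []
    for i in keep:
        if len(cols) == insert_at:
            cols.append(aligned)
            names.append("aligned")
        cols.append(base.matrix[:, i])
        names.append(base.names[i])
    return DesignMatrix(np.column_stack(cols), names, tr=tr, fold=k)


def build_crossval_test_design(
    events_est: pd.DataFrame,
    events_test: pd.DataFrame,
    k: int,
    phi_bar: float,
    n_scans: int,
    cut_scan: int,
    tr: float,
    est_base: Optional[DesignMatrix] = None,
    test_base: Optional[DesignMatrix] = None,
) -> DesignMatrix:
    """Test-half (GLM2) design with carry-over nuisance regressors.

    The hemodynamic tails of estimation-half events bleed past the split
    boundary, so the test model is built on the full-run timeline and then
    restricted to scans >= ``cut_scan``: the estimation half's translation
    boxcar, quadrature pair and rotation boxcar enter as nuisance columns
    alongside the test half's own translation/rotation boxcars and the
    aligned modulator cos(k*(phi - phi_bar)).  With this carry-over set a
    noiseless planted run is an exact linear combination of the columns.

    ``events_test`` keeps original (full-run) onsets.  ``est_base`` and
    ``test_base`` may supply previously built full-timeline quadrature
    designs for the two event subsets.
    """
    if est_base is None:
        est_base = build_design(events_est, k, n_scans, tr)
    if test_base is None:
        test_base = build_design(events_test, k, n_scans, tr)
    a = np.deg2rad(k * phi_bar)
    aligned = np.cos(a) * test_base.column("cos") + np.sin(a) * test_base.column("sin")
    cols = [np.ones(n_scans)]
    names = ["intercept"]
    for src, prefix, wanted in (
        (est_base, "est_", ("translation", "sin", "cos", "rotation")),
        (test_base, "", ("translation",)),
    ):
        for nm in wanted:
            if nm in src.names:
                cols.append(src.column(nm))
                names.append(prefix + nm)
    cols.append(aligned)
    names.append("aligned")
    if "rotation" in test_base.names:
        cols.append(test_base.column("rotation"))
        names.append("rotation")
    for nm in est_base.names:
        if nm.startswith(("drift", "dct")):
            cols.append(est_base.column(nm))
            names.append(nm)
    matrix = np.column_stack(cols)[cut_scan:]
    # carry-over columns can vanish on the restricted rows; drop them
    keep = [
        i
        for i, nm in enumerate(names)
        if nm in ("intercept", "aligned") or np.abs(matrix[:, i]).max() > 1e-10
    ]
    matrix = matrix[:, keep]
    names = [names[i] for i in keep]
    # Restricted to the post-boundary rows the boxcars can tile the window
    # (translations and rotations alternate without gaps), making their sum
    # constant and hence collinear with the intercept.  Drop redundant
    # nuisance columns until the design has full rank; the intercept and the
    # aligned modulator are never dropped.
    matrix, names = _prune_collinear(matrix, names, protected=("intercept", "aligned"))
    return DesignMatrix(matrix, names, tr=tr, fold=k)


def _prune_collinear(matrix, names, protected=()):
    while np.linalg.matrix_rank(matrix) < matrix.shape[1]:
        rank = np.linalg.matrix_rank(matrix)
        for i in range(matrix.shape[1] - 1, -1, -1):
            if names[i] in protected:
                continue
            reduced = np.delete(matrix, i, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                matrix = reduced
                names = names[:i] + names[i + 1 :]
                break
        else:
            raise DesignError("design rank-deficient among protected columns")
    return matrix, names
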