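"""Temporal signal-to-noise (tSNR) voxel screening.

tSNR is each voxel's temporal mean divided by its temporal standard
deviation.  Voxels are excluded when their tSNR falls more than 1.5
interquartile ranges below the first quartile of the within-subject tSNR
distribution, or when tSNR is undefined (constant series).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class QCResult:
    tsnr: np.ndarray  # NaN where undefined
    q1: float
    iqr: float
    threshold: float  # q1 - 1.5 * iqr
    excluded: np.ndarray  # indices of excluded voxels
    keep: np.ndarray  # boolean mask of retained voxels


def tsnr_filter(run_or_data) -> QCResult:
    """Compute per-voxel tSNR and the Q1 - 1.5*IQR exclusion rule.

    Quartiles use linear interpolation over the defined tSNR values.
    """
    data = np.asarray(getattr(run_or_data, "data", run_or_data), dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("need a voxels x scans array with at least 2 scans")
    mean = data.mean(axis=1)
    sd = data.std(axis=1, ddof=1)
    tsnr = np.full(data.shape[0], np.nan)
    defined = sd > 0
    tsnr[defined] = mean[defined] / sd[defined]
    if defined.sum() == 0:
        return QCResult(
            tsnr=tsnr,
            q1=np.nan,
            iqr=np.nan,
            threshold=np.nan,
            excluded=np.arange(data.shape[0]),
            keep=np.zeros(data.shape[0], dtype=bool),
        )
    q1, q3 = np.percentile(tsnr[defined], [25.0, 75.0])
    iqr = q3 - q1
    threshold = q1 - 1.5 * iqr
    keep = defined & (tsnr >= threshold)
    # NaN comparisons are False, so undefined voxels are excluded automatically
    return QCResult(
        tsnr=tsnr,
        q1=float(q1),
        iqr=float(iqr),
        threshold=float(threshold),
        excluded=np.flatnonzero(~keep),
        keep=keep,
    )
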