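"""Per-voxel ordinary-least-squares fitting of design matrices."""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
from scipy import linalg

from .design import DesignError, DesignMatrix


@dataclass
class GlmFit:
    """OLS fit of one design to many voxels."""

    betas: np.ndarray  # voxels x regressors, in design column order
    resid_var: np.ndarray  # per voxel, SSE / df
    df: int
    names: List[str]

    def beta(self, name: str) -> np.ndarray:
        return self.betas[:, self.names.index(name)]


def _collinear_columns(x: np.ndarray, names: List[str], rank: int) -> List[str]:
    _, r, piv = linalg.qr(x, mode="economic", pivoting=True)
    return sorted(names[i] for i in piv[rank:])


def fit_glm(run_or_data, design: DesignMatrix) -> GlmFit:
    """Fit the design to every voxel by ordinary least squares.

    ``run_or_data`` is a BoldRun or a voxels x scans array.  Raises
    :class:`DesignError` naming the collinear columns if the design is
    rank-deficient, or if degrees of freedom would be non-positive.
    """
    data = np.asarray(getattr(run_or_data, "data", run_or_data), dtype=float)
    if data.ndim == 1:
        data = data[None, :]
    x = design.matrix
    if data.shape[1] != x.shape[0]:
        raise DesignError(
            f"data has {data.shape[1]} scans but the design has {x.shape[0]} rows"
        )
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        bad = _collinear_columns(x, design.names, rank)
        raise DesignError(f"design is rank-deficient; collinear columns: {bad}")
    df = x.shape[0] - rank
    if df <= 0:
        raise DesignError("no residual degrees of freedom")
    betas, _, _, _ = np.linalg.lstsq(x, data.T, rcond=None)
    resid = data.T - x @ betas
    resid_var = np.einsum("ij,ij->j", resid, resid) / df
    return GlmFit(betas=betas.T, resid_var=resid_var, df=df, names=list(design.names))
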