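"""Temporal and spatial stability of voxel grid orientations.

Temporal stability: the fraction of voxels whose orientation moves by at
most ``tolerance`` degrees (in the fold's periodic space) between the two
data halves.  For k = 6 and +-15 degrees the chance level is
2 * 15 / 60 = 50%.

Spatial stability: Rayleigh's test for non-uniformity of the voxel
orientations within an ROI, computed on the doubled angles k * theta_v,
unweighted.  Z = n * R_bar**2; higher Z means stronger clustering around a
shared orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .circular import circ_dist, period, rayleigh_test


@dataclass
class StabilityResult:
    fold: int
    n_voxels: int
    temporal_fraction: Optional[float] = None
    chance_level: Optional[float] = None
    tolerance: Optional[float] = None
    n_undefined: int = 0
    rayleigh_z: Optional[float] = None
    rayleigh_p: Optional[float] = None
    resultant: Optional[float] = None


def temporal_stability(
    theta_half1,
    theta_half2,
    k: int,
    tolerance: Optional[float] = None,
) -> StabilityResult:
    """Fraction of voxels with |circular distance| <= tolerance between halves.

    ``tolerance`` defaults to a quarter period, (360/k)/4, i.e. +-15 degrees
    for the 6-fold model.  Voxels with an undefined orientation (NaN) in
    either half are dropped from the denominator and counted separately.
    """
    if tolerance is None:
        tolerance = period(k) / 4.0
    t1 = np.asarray(theta_half1, dtype=float)
    t2 = np.asarray(theta_half2, dtype=float)
    if t1.shape != t2.shape:
        raise ValueError("orientation vectors must have equal length")
    if t1.size == 0:
        raise ValueError("no orientations supplied")
    ok = np.isfinite(t1) & np.isfinite(t2)
    n_undefined = int((~ok).sum())
    if ok.sum() == 0:
        raise ValueError("no voxel has a defined orientation in both halves")
    stable = circ_dist(t1[ok], t2[ok], k) <= tolerance
    return StabilityResult(
        fold=k,
        n_voxels=int(ok.sum()),
        temporal_fraction=float(stable.mean()),
        chance_level=2.0 * tolerance / period(k),
        tolerance=float(tolerance),
        n_undefined=n_undefined,
    )


def spatial_stability(theta, k: int) -> StabilityResult:
    """Rayleigh non-uniformity test of voxel orientations in k-fold space."""
    t = np.asarray(theta, dtype=float)
    t = t[np.isfinite(t)]
    if t.size < 2:
        raise ValueError("Rayleigh test requires at least 2 defined orientations")
    z, p, r_bar = rayleigh_test(np.deg2rad(k * t))
    return StabilityResult(
        fold=k, n_voxels=int(t.size), rayleigh_z=z, rayleigh_p=p, resultant=r_bar
    )
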